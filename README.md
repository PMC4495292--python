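# phospho1433

Prediction of 14-3-3-binding phosphosites from Ser/Thr-centred sequence
windows.

14-3-3 proteins are dimeric adaptors that dock onto pairs of
phosphorylated Ser/Thr residues and thereby regulate a large fraction of
intracellular signalling.  Which phosphosites they bind is strongly
determined by the residues immediately flanking the phospho-acceptor —
classically the Mode I motif RSX(pS/T)XP — but curated binding sites are
far more diverse than the classical motifs.  `phospho1433` is a toolkit
for training and applying sequence-window classifiers of 14-3-3 binding:
it is aimed at computational biologists who want to rank candidate
binding sites in a protein or proteome, benchmark site predictors, or
prototype motif classifiers on controlled synthetic data.

## The models

A candidate site is a window `[-a:+b]` around the phospho-Ser/Thr
(canonically `[-6:+4]`, flank width k = 10), padded with `X` at protein
termini.  Three classifiers score a window `p`, and a consensus averages
them:

* **PSSM** — 21×k frequency matrices from binder (POS), non-binder (NEG)
  and background (BGD) peptides, scored additively over flank columns:

  `S(p) = Σ_j (POS[i(j),j] − NEG[i(j),j]) / BGD[i(j),j]`

* **ANN** — one-hot encoded window (20 inputs per residue, `X` = zeros),
  one hidden layer of 20 sigmoid units, online backpropagation with
  momentum (η = 0.2, µ = 0.05).

* **SVM** — weighted-degree string kernel
  `K(x,y) = Σ_{m≤d} β_m · #{l : x[l:l+m] = y[l:l+m]}` (d = 3,
  β_m = 2(d−m+1)/(d(d+1))), cosine-normalised, soft margin C = 1.

* **Consensus** — the arithmetic mean of the three raw scores.  Default
  decision cut-offs: 0.55 (ANN), 0.80 (PSSM), 0.25 (SVM), 0.50
  (consensus), with the call rule `score ≥ cut-off`.

Supporting modules provide window extraction from FASTA + phosphosite
lists, combinatorial redundancy filtering for short peptides, jackknife
(leave-one-out) evaluation with ROC/AUC and the SN/SP/PPV/ACC/MCC panel,
paired-bootstrap MCC comparisons, proteome scanning, and a seeded
synthetic generator of Mode-I-style binder/non-binder peptides.  See
`docs/methods.md` for the full model description and design rationale.

## Worked example

Generate a synthetic training table, train all three models, and score
peptides (the library API mirrors every step; `phospho1433 --help` lists
the subcommands):

```bash
$ phospho1433 simulate --n-pos 318 --n-neg 318 --seed 7 --out peptides.tsv
wrote 636 peptides to peptides.tsv

$ phospho1433 train --peptides peptides.tsv --min-diff 1 --epochs 5 \
      --seed 7 --out-dir models
models and training report written to models

$ phospho1433 predict GLRRSNSAPLI TLRRSSSAPLI AAAAAASAAAA --models models
peptide      ann       pssm       svm       consensus  ann_call  pssm_call  svm_call  consensus_call
GLRRSNSAPLI  0.967322  17.283186  1.955633  6.735380   1         1          1         1
TLRRSSSAPLI  0.978417  18.769912  2.039009  7.262446   1         1          1         1
AAAAAASAAAA  0.025592  -2.292035  -1.257063 -1.174502  0         0          0         0
```

The first two peptides are the Mode-I-like sites of a 14-3-3-binding
protein family (Arg at −3, Pro at +2 relative to the central Ser): all
four methods call them binders, with the unbounded PSSM term dominating
the consensus magnitude.  The poly-Ala control scores below every
cut-off.  Scanning a FASTA ranks every Ser/Thr site by consensus score:

```bash
$ phospho1433 scan --fasta prot.fasta --models models --threshold 0.5 --out scan.tsv
scanned 43 sites; 12 predicted (27.9%) in 4 proteins (mean 3.00 sites/protein)

$ head -4 scan.tsv | tail -2   # rank, site, motif, per-method scores, calls
1  SYN0000  51  T  IPCRSATQPHN  0.981335  19.513274  2.542685  7.679098  1  1  1  1
2  SYN0001  51  S  GNQYSSSCPGQ  0.856495  9.415929   0.707763  3.660063  1  1  1  1
```

`evaluate` produces a benchmark-style report (confusion counts, the five
metrics and a paired-bootstrap p-value of each method against the
consensus) for any labelled peptide table, and `--sites` restricts scans
to an annotated phosphoproteome.

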