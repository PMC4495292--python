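"""Proteome scanning: enumerate Ser/Thr sites, score, rank, summarise.

Every S/T in every protein is a candidate site; supplying a phosphosite
list restricts scoring to annotated sites (the phosphoproteome), which
sharply reduces candidate numbers and false positives.  Records are ranked
by consensus score (descending), ties broken by accession then position.
Sites at the very termini, whose windows are mostly padding, are still
scored: C-terminal penultimate-residue (Mode III) binding sites are real.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .consensus import ModelBundle, PredictionRecord, score_all_many
from .peptides import Phosphosite, extract_window, read_fasta
from .peptides import CENTER_RESIDUES

logger = logging.getLogger(__name__)


def enumerate_st_sites(sequence: str) -> list[int]:
    """All 1-based positions carrying Ser or Thr, ascending."""
    return [
        i for i, c in enumerate(sequence.upper(), start=1) if c in CENTER_RESIDUES
    ]


@dataclass(frozen=True)
class ScanSummary:
    """Site- and protein-level counts for one scan at one threshold."""

    n_scanned: int
    n_predicted: int
    n_proteins_predicted: int
    fraction_predicted: float
    mean_sites_per_protein: float


def scan_proteome(
    sequences: Mapping[str, str] | str | Path,
    bundle: ModelBundle,
    phosphosites: Iterable[Phosphosite] | None = None,
    threshold: float | None = None,
) -> list[PredictionRecord]:
    """Score candidate Ser/Thr sites in a proteome with all three methods.

    ``sequences`` is an accession -> sequence mapping or a FASTA path.
    Without ``phosphosites`` every S/T is scored; with it, only listed sites
    are (accessions absent from the FASTA, or annotations disagreeing with
    the sequence, are logged and skipped).  Records come back sorted by
    consensus score descending, ties by accession then position.
    """
    if not isinstance(sequences, Mapping):
        sequences = read_fasta(sequences)
    spec = bundle.window_spec
    if threshold is None:
        threshold = bundle.consensus_threshold

    sites: list[tuple[str, int]] = []
    if phosphosites is None:
        for acc in sequences:
            sites.extend((acc, pos) for pos in enumerate_st_sites(sequences[acc]))
    else:
        for site in phosphosites:
            if site.accession not in sequences:
                logger.warning(
                    "accession %r not in FASTA; site %d skipped",
                    site.accession, site.position,
                )
                continue
            seq = sequences[site.accession]
            if (
                site.position > len(seq)
                or seq[site.position - 1].upper() != site.residue
            ):
                logger.warning(
                    "%s:%d annotation disagrees with sequence; skipped",
                    site.accession, site.position,
                )
                continue
            sites.append((site.accession, site.position))

    if not sites:
        return []
    windows = [
        extract_window(sequences[acc], pos, spec) for acc, pos in sites
    ]
    scores = score_all_many(bundle, windows)
    records = []
    for i, (acc, pos) in enumerate(sites):
        motif = windows[i].sequence
        a, p, s, c = (
            float(scores["ann"][i]),
            float(scores["pssm"][i]),
            float(scores["svm"][i]),
            float(scores["consensus"][i]),
        )
        records.append(
            PredictionRecord(
                accession=acc,
                position=pos,
                residue=motif[spec.left],
                motif=motif,
                ann=a,
                pssm=p,
                svm=s,
                consensus=c,
                ann_call=a >= bundle.ann.threshold,
                pssm_call=p >= bundle.pssm.threshold,
                svm_call=s >= bundle.svm.threshold,
                consensus_call=c >= threshold,
            )
        )
    records.sort(key=lambda r: (-r.consensus, r.accession, r.position))
    return records


def summarize_scan(
    records: Sequence[PredictionRecord], threshold: float
) -> ScanSummary:
    """Counts of predicted sites/proteins at a consensus threshold.

    The mean sites-per-protein averages over proteins with at least one
    prediction.
    """
    n_scanned = len(records)
    predicted = [r for r in records if r.consensus >= threshold]
    per_protein: dict[str, int] = {}
    for r in predicted:
        per_protein[r.accession] = per_protein.get(r.accession, 0) + 1
    n_pred = len(predicted)
    n_prot = len(per_protein)
    return ScanSummary(
        n_scanned=n_scanned,
        n_predicted=n_pred,
        n_proteins_predicted=n_prot,
        fraction_predicted=n_pred / n_scanned if n_scanned else 0.0,
        mean_sites_per_protein=n_pred / n_prot if n_prot else 0.0,
    )


def write_records(
    records: Sequence[PredictionRecord], path, header_comment: str | None = None
) -> None:
    """Write ranked prediction records as TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "rank\taccession\tposition\tresidue\tmotif\tann\tpssm\tsvm\t"
            "consensus\tann_call\tpssm_call\tsvm_call\tconsensus_call\n"
        )
        for rank, r in enumerate(records, start=1):
            fh.write(
                f"{rank}\t{r.accession}\t{r.position}\t{r.residue}\t{r.motif}\t"
                f"{r.ann:.6f}\t{r.pssm:.6f}\t{r.svm:.6f}\t{r.consensus:.6f}\t"
                f"{int(r.ann_call)}\t{int(r.pssm_call)}\t{int(r.svm_call)}\t"
                f"{int(r.consensus_call)}\n"
            )
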