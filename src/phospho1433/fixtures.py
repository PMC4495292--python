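"""Synthetic labelled phosphopeptide generator.

Emulates the dominant ("Mode I"-like) positional signal of curated
14-3-3-binding phosphopeptides against i.i.d. background negatives:

* positives: Arg set at position -3 with probability 0.46 and Pro at +2
  with probability 0.31, plus the weaker secondary preferences of curated
  binder sets — Ser at -2 (0.25) and Leu at +1 (0.20); Pro never appears
  at +1 (hard negative determinant); every other flank is a background
  draw; the central residue is S or T with equal probability;
* negatives: central S/T with all flanks i.i.d. from the background.

The two strong set-probabilities correspond to the reported ~46% Arg(-3)
and ~31% Pro(+2) enrichment of real binder sets, read as absolute
positive-class frequencies; the Ser(-2)/Leu(+1) preferences are reported
only qualitatively ("poorer" enrichment) and their probabilities here are
fixed package choices below the quantified pair.  Together these place the
generator's Bayes-optimal separability at AUC ~0.87, matching the
separability observed for real binder/non-binder sets.  The background
defaults to uniform over the 20 residues rather than proteome composition,
keeping the generator self-contained; a composition vector can override
it.

Positives, negatives and background windows draw from disjoint seeded
streams, so datasets are byte-for-byte reproducible and independently
extensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peptides import (
    AA20,
    ALPHABET,
    LabelledDataset,
    PeptideWindow,
    Phosphosite,
    ValidationError,
    WindowSpec,
)
from .pssm import build_frequency_matrix


def _default_enrichments() -> dict[int, tuple[str, float]]:
    return {-3: ("R", 0.46), -2: ("S", 0.25), 1: ("L", 0.20), 2: ("P", 0.31)}


def _default_forbidden() -> dict[int, str]:
    return {1: "P"}


@dataclass
class GeneratorConfig:
    """Sampling parameters for synthetic POS/NEG peptide sets.

    Defaults mirror the composition of the curated training data this
    generator stands in for: 318 peptides per class, a [-6:+4] window, and
    the Mode-I positional biases above.
    """

    n_pos: int = 318
    n_neg: int = 318
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    seed: int = 0
    enrichments: dict[int, tuple[str, float]] = field(
        default_factory=_default_enrichments
    )
    forbidden: dict[int, str] = field(default_factory=_default_forbidden)
    background: Sequence[float] | None = None  # composition over AA20

    def __post_init__(self) -> None:
        for off, (res, p) in self.enrichments.items():
            if res not in AA20:
                raise ValidationError(f"enrichment residue {res!r} not standard")
            if not 0 <= p <= 1:
                raise ValidationError(f"enrichment probability {p} outside [0, 1]")
            if self.forbidden.get(off) == res and p > 0:
                raise ValidationError(
                    f"residue {res!r} both enriched and forbidden at {off:+d}"
                )
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or (bg < 0).any() or not np.isclose(bg.sum(), 1.0):
                raise ValidationError(
                    "background must be 20 non-negative frequencies summing to 1"
                )

    def background_vector(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20.0)
        return np.asarray(self.background, dtype=float)


_AA20_ARR = np.array(list(AA20))


def _draw_background(rng: np.random.Generator, n: int, k: int, bg: np.ndarray) -> np.ndarray:
    return rng.choice(_AA20_ARR, size=(n, k), p=bg)


def _centers(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.where(rng.random(n) < 0.5, "S", "T")


def _assemble(flanks: np.ndarray, centers: np.ndarray, spec: WindowSpec, label: str) -> LabelledDataset:
    windows = []
    for row, c in zip(flanks, centers):
        seq = "".join(row[: spec.left]) + str(c) + "".join(row[spec.left :])
        windows.append(PeptideWindow(seq, label=label))
    return LabelledDataset(windows, spec)


def generate_positives(config: GeneratorConfig) -> LabelledDataset:
    """Sample n_pos Mode-I-biased binder peptides (label POS)."""
    spec = config.window_spec
    rng = np.random.default_rng([config.seed, 1])
    bg = config.background_vector()
    offsets = spec.offsets()
    flanks = _draw_background(rng, config.n_pos, spec.width, bg)
    col = {off: j for j, off in enumerate(offsets)}
    for off, (res, p) in config.enrichments.items():
        if off not in col:
            continue
        hit = rng.random(config.n_pos) < p
        flanks[hit, col[off]] = res
    for off, res in config.forbidden.items():
        if off not in col:
            continue
        i = AA20.index(res)
        mass = bg.copy()
        mass[i] = 0.0
        if mass.sum() <= 0:
            raise ValidationError(
                f"background leaves no residue allowed at {off:+d}"
            )
        mass /= mass.sum()
        bad = flanks[:, col[off]] == res
        if bad.any():
            flanks[bad, col[off]] = rng.choice(_AA20_ARR, size=int(bad.sum()), p=mass)
    return _assemble(flanks, _centers(rng, config.n_pos), spec, "POS")


def generate_negatives(config: GeneratorConfig) -> LabelledDataset:
    """Sample n_neg background peptides around a central S/T (label NEG)."""
    spec = config.window_spec
    rng = np.random.default_rng([config.seed, 2])
    flanks = _draw_background(rng, config.n_neg, spec.width, config.background_vector())
    return _assemble(flanks, _centers(rng, config.n_neg), spec, "NEG")


def generate_dataset(config: GeneratorConfig) -> LabelledDataset:
    """Positives followed by negatives, one LabelledDataset."""
    pos = generate_positives(config)
    neg = generate_negatives(config)
    return LabelledDataset(pos.windows + neg.windows, config.window_spec)


def generate_background_windows(config: GeneratorConfig, n: int) -> list[str]:
    """i.i.d. background windows (central S/T) for building a BGD matrix."""
    spec = config.window_spec
    rng = np.random.default_rng([config.seed, 3])
    flanks = _draw_background(rng, n, spec.width, config.background_vector())
    centers = _centers(rng, n)
    return [
        "".join(row[: spec.left]) + str(c) + "".join(row[spec.left :])
        for row, c in zip(flanks, centers)
    ]


def position_enrichment(
    pos: LabelledDataset, neg: LabelledDataset
) -> pd.DataFrame:
    """Per-position differential residue frequencies, freq_POS - freq_NEG.

    Rows are the 21 alphabet symbols, columns the flank offsets
    (-left..-1, +1..+right).  Raw frequencies (pseudocount 0) so that
    identical inputs give exact zeros.
    """
    if pos.window_spec != neg.window_spec:
        raise ValidationError("POS and NEG datasets must share one window spec")
    spec = pos.window_spec
    fp = build_frequency_matrix(pos, spec, "POS", pseudocount=0.0)
    fn = build_frequency_matrix(neg, spec, "NEG", pseudocount=0.0)
    return pd.DataFrame(
        fp.values - fn.values, index=list(ALPHABET), columns=spec.offsets()
    )


def generate_proteome(
    n_proteins: int = 12,
    length: int = 200,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    implant: bool = True,
) -> tuple[dict[str, str], list[Phosphosite]]:
    """A small synthetic proteome with optional implanted binder motifs.

    Each protein is an i.i.d. background sequence; with ``implant`` one
    positive-style window is written into the middle of every protein.
    Returns the sequences plus the phosphosites of the implanted (or, when
    not implanting, the first) S/T site of each protein for restriction-mode
    scans.  Purely synthetic scaffolding for tests and demos.
    """
    config = config or GeneratorConfig()
    spec = config.window_spec
    rng = np.random.default_rng([seed, 4])
    bg = config.background_vector()
    implant_cfg = GeneratorConfig(
        n_pos=n_proteins,
        n_neg=0,
        window_spec=spec,
        seed=seed + 17,
        enrichments=config.enrichments,
        forbidden=config.forbidden,
        background=config.background,
    )
    motifs = generate_positives(implant_cfg).sequences() if implant else []
    sequences: dict[str, str] = {}
    sites: list[Phosphosite] = []
    for i in range(n_proteins):
        acc = f"SYN{i:04d}"
        chars = rng.choice(_AA20_ARR, size=length, p=bg)
        if implant:
            center = length // 2  # 0-based centre of the implanted window
            start = center - spec.left
            for j, c in enumerate(motifs[i]):
                chars[start + j] = c
            sites.append(Phosphosite(acc, center + 1, str(chars[center])))
        seq = "".join(chars)
        if not implant:
            for pos_1b, c in enumerate(seq, start=1):
                if c in ("S", "T"):
                    sites.append(Phosphosite(acc, pos_1b, c))
                    break
        sequences[acc] = seq
    return sequences, sites
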