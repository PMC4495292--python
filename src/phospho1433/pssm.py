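"""Position-specific scoring matrix classifier.

Three 21-row x k-column frequency matrices are built from peptide windows:
POS (binder peptides), NEG (non-binder peptides) and BGD (a background set,
typically all phosphoproteome S/T windows).  A query peptide p is scored by

    S(p) = sum_j (POS[i(j), j] - NEG[i(j), j]) / BGD[i(j), j]

where i(j) is the residue of p at flank column j.  The sum runs over the k
flanking columns only: the central S/T is excluded, consistent with the
k-column matrix definition (k counts flanks).  Scores are unbounded and
additive over columns.

Because the score divides by background frequencies, all matrices are
Laplace-smoothed by default (pseudocount 1 per cell before normalisation);
a pseudocount of 0 is supported for exact hand-checkable matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .peptides import (
    AA_INDEX,
    ALPHABET,
    LabelledDataset,
    PeptideWindow,
    ValidationError,
    WindowSpec,
)

ROLES = ("POS", "NEG", "BGD")

DEFAULT_PSSM_THRESHOLD = 0.80


def _flank_strings(windows, spec: WindowSpec) -> list[str]:
    """Flank sequences (centre removed) from windows, flank strings or a dataset."""
    if isinstance(windows, LabelledDataset):
        items: Iterable = windows.windows
    else:
        items = windows
    out = []
    for w in items:
        s = w.sequence if isinstance(w, PeptideWindow) else str(w)
        if len(s) == spec.full_width:
            s = s[: spec.left] + s[spec.left + 1 :]
        elif len(s) != spec.width:
            raise ValidationError(
                f"peptide {s!r} has width {len(s)}; expected {spec.full_width} "
                f"(full window) or {spec.width} (flanks) for {spec}"
            )
        out.append(s)
    return out


def _index_matrix(flanks: Sequence[str]) -> np.ndarray:
    """(n, k) matrix of alphabet indices for flank strings."""
    return np.array(
        [[AA_INDEX[c] for c in s] for s in flanks], dtype=np.intp
    )


@dataclass
class FrequencyMatrix:
    """Per-position residue frequencies: 21 alphabet rows x k window columns."""

    values: np.ndarray
    role: str
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.values.ndim != 2 or self.values.shape[0] != len(ALPHABET):
            raise ValidationError(
                f"frequency matrix must have {len(ALPHABET)} rows, "
                f"got shape {self.values.shape}"
            )
        if (self.values < 0).any():
            raise ValidationError("frequencies must be non-negative")
        sums = self.values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError(
                f"every column must sum to 1; got sums {sums}"
            )

    @property
    def k(self) -> int:
        return self.values.shape[1]


def build_frequency_matrix(
    windows, spec: WindowSpec, role: str, pseudocount: float = 1.0
) -> FrequencyMatrix:
    """Count residues per flank column and normalise with Laplace smoothing.

    frequency(i, j) = (count(i, j) + pseudocount) / (n + 21 * pseudocount)
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    flanks = _flank_strings(windows, spec)
    if not flanks:
        raise ValidationError("cannot build a frequency matrix from an empty peptide set")
    idx = _index_matrix(flanks)
    n, k = idx.shape
    counts = np.zeros((len(ALPHABET), k))
    cols = np.broadcast_to(np.arange(k), idx.shape)
    np.add.at(counts, (idx, cols), 1.0)
    values = (counts + pseudocount) / (n + len(ALPHABET) * pseudocount)
    return FrequencyMatrix(values, role=role, pseudocount=pseudocount)


def uniform_background(spec: WindowSpec) -> FrequencyMatrix:
    """A flat background: every symbol 1/21 at every column."""
    values = np.full((len(ALPHABET), spec.width), 1.0 / len(ALPHABET))
    return FrequencyMatrix(values, role="BGD")


@dataclass
class PssmModel:
    """POS/NEG/BGD matrices plus window spec and decision threshold."""

    pos: FrequencyMatrix
    neg: FrequencyMatrix
    bgd: FrequencyMatrix
    window_spec: WindowSpec
    threshold: float = DEFAULT_PSSM_THRESHOLD

    def __post_init__(self) -> None:
        k = self.window_spec.width
        for m in (self.pos, self.neg, self.bgd):
            if m.k != k:
                raise ValidationError(
                    f"matrix with k={m.k} does not match window {self.window_spec}"
                )
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")


def train_pssm(
    dataset: LabelledDataset,
    background: FrequencyMatrix | Sequence[str] | None = None,
    pseudocount: float = 1.0,
    threshold: float = DEFAULT_PSSM_THRESHOLD,
) -> PssmModel:
    """Build a PssmModel from a labelled dataset and a background.

    ``background`` may be a ready FrequencyMatrix, a collection of peptide
    windows (e.g. phosphoproteome S/T windows), or None for a flat 1/21
    background.
    """
    spec = dataset.window_spec
    pos_ds = dataset.by_label("POS")
    neg_ds = dataset.by_label("NEG")
    pos = build_frequency_matrix(pos_ds, spec, "POS", pseudocount)
    neg = build_frequency_matrix(neg_ds, spec, "NEG", pseudocount)
    if background is None:
        bgd = uniform_background(spec)
    elif isinstance(background, FrequencyMatrix):
        bgd = background
    else:
        bgd = build_frequency_matrix(background, spec, "BGD", pseudocount)
    return PssmModel(pos, neg, bgd, spec, threshold)


def score_many(model: PssmModel, peptides) -> np.ndarray:
    """Vectorised PSSM scores for a batch of windows (or flank strings)."""
    flanks = _flank_strings(peptides, model.window_spec)
    if not flanks:
        return np.empty(0)
    idx = _index_matrix(flanks)
    cols = np.broadcast_to(np.arange(idx.shape[1]), idx.shape)
    bgd_vals = model.bgd.values[idx, cols]
    if (bgd_vals == 0).any():
        raise ValidationError(
            "background frequency is zero at a scored cell; rebuild the "
            "matrices with a positive pseudocount"
        )
    num = model.pos.values[idx, cols] - model.neg.values[idx, cols]
    return (num / bgd_vals).sum(axis=1)


def pssm_score(model: PssmModel, peptide) -> float:
    """Score a single peptide window by the summed per-column frequency ratios."""
    return float(score_many(model, [peptide])[0])


def pssm_classify(model: PssmModel, peptide, threshold: float | None = None) -> bool:
    """Binding call: score >= threshold (model default 0.80)."""
    t = model.threshold if threshold is None else threshold
    return pssm_score(model, peptide) >= t


# ---------------------------------------------------------------------------
# plain-text serialization: three labelled 21 x k blocks plus a header


def save_pssm(model: PssmModel, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"window\t{model.window_spec.left}\t{model.window_spec.right}\n")
        fh.write(f"threshold\t{model.threshold!r}\n")
        for mat in (model.pos, model.neg, model.bgd):
            fh.write(f"[{mat.role}]\tpseudocount={mat.pseudocount!r}\n")
            for aa, row in zip(ALPHABET, mat.values):
                fh.write(aa + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_pssm(path) -> PssmModel:
    path = Path(path)
    spec: WindowSpec | None = None
    threshold = DEFAULT_PSSM_THRESHOLD
    mats: dict[str, FrequencyMatrix] = {}
    role: str | None = None
    pc = 0.0
    rows: list[list[float]] = []

    def _flush() -> None:
        nonlocal rows, role
        if role is not None:
            mats[role] = FrequencyMatrix(np.array(rows), role=role, pseudocount=pc)
        rows = []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("window\t"):
                _, left, right = line.split("\t")
                spec = WindowSpec(int(left), int(right))
            elif line.startswith("threshold\t"):
                threshold = float(line.split("\t")[1])
            elif line.startswith("["):
                _flush()
                head, _, meta = line.partition("\t")
                role = head.strip("[]")
                pc = float(meta.split("=")[1]) if "=" in meta else 0.0
            else:
                parts = line.split("\t")
                rows.append([float(v) for v in parts[1:]])
    _flush()
    if spec is None or set(mats) != set(ROLES):
        raise ValidationError(f"{path}: incomplete PSSM model file")
    return PssmModel(mats["POS"], mats["NEG"], mats["BGD"], spec, threshold)
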