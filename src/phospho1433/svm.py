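"""Weighted-degree string kernel and soft-margin SVM over peptide windows.

The weighted-degree kernel compares two equal-length peptides by counting
exactly matching substrings at corresponding positions:

    K(x, y) = sum_{m=1..d} beta_m * sum_{l=1..L-m+1} [x[l:l+m] == y[l:l+m]]

with the canonical decreasing weights beta_m = 2(d-m+1) / (d(d+1)),
which sum to 1.  Degree d = 3 by default (mono-, di- and tri-peptide
features).  'X' is a literal symbol that matches only itself, so shared
terminal padding counts as similarity — meaningful for C-terminal
(penultimate-residue) binding sites.

Kernel values are cosine-normalised, K^(x,y) = K(x,y)/sqrt(K(x,x)K(y,y)).
Because every substring matches itself, K(x,x) = sum_m beta_m (L-m+1) is a
constant for fixed length L, so normalisation is a fixed rescaling for
equal-length windows.

The soft-margin dual (C = 1 by default) is solved with scikit-learn's SVC
on the precomputed normalised kernel; the model keeps only the support
peptides, their dual coefficients alpha_i * y_i, and the bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .peptides import (
    LabelledDataset,
    PeptideWindow,
    ValidationError,
    WindowSpec,
)

DEFAULT_SVM_THRESHOLD = 0.25


@dataclass(frozen=True)
class SvmConfig:
    """Kernel degree/weights and soft-margin constant."""

    degree: int = 3
    c: float = 1.0
    threshold: float = DEFAULT_SVM_THRESHOLD
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValidationError("degree must be >= 1")
        if self.c <= 0:
            raise ValidationError("C must be > 0")
        if self.weights is not None and len(self.weights) != self.degree:
            raise ValidationError(
                f"need {self.degree} substring weights, got {len(self.weights)}"
            )

    @property
    def beta(self) -> np.ndarray:
        """Substring weights beta_1..beta_d (default 2(d-m+1)/(d(d+1)))."""
        if self.weights is not None:
            return np.asarray(self.weights, dtype=float)
        d = self.degree
        return np.array([2.0 * (d - m + 1) / (d * (d + 1)) for m in range(1, d + 1)])


def _seqs(peptides) -> list[str]:
    if isinstance(peptides, LabelledDataset):
        peptides = peptides.windows
    return [
        p.sequence if isinstance(p, PeptideWindow) else str(p) for p in peptides
    ]


def _char_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), len(seqs[0])
    )


def self_kernel(length: int, config: SvmConfig | None = None) -> float:
    """K(x, x) for any peptide of the given length: sum_m beta_m (L-m+1)."""
    config = config or SvmConfig()
    beta = config.beta
    return float(
        sum(b * (length - m + 1) for m, b in enumerate(beta, start=1) if m <= length)
    )


def kernel_matrix(
    x_peptides, y_peptides, config: SvmConfig | None = None, normalize: bool = True
) -> np.ndarray:
    """Weighted-degree kernel between two peptide collections, vectorised.

    Returns the (n_x, n_y) matrix; with ``normalize`` the cosine-normalised
    values are returned (identical peptides score 1).
    """
    config = config or SvmConfig()
    xs, ys = _seqs(x_peptides), _seqs(y_peptides)
    if not xs or not ys:
        return np.zeros((len(xs), len(ys)))
    lx, ly = len(xs[0]), len(ys[0])
    if any(len(s) != lx for s in xs) or any(len(s) != ly for s in ys):
        raise ValidationError("all peptides in a collection must share one width")
    if lx != ly:
        raise ValidationError(f"cannot compare widths {lx} and {ly}")
    x = _char_matrix(xs)
    y = _char_matrix(ys)
    eq = x[:, None, :] == y[None, :, :]
    beta = config.beta
    k = beta[0] * eq.sum(axis=-1, dtype=float)
    run = eq
    for m in range(2, config.degree + 1):
        if m > lx:
            break
        run = run[:, :, :-1] & eq[:, :, m - 1 :]
        k += beta[m - 1] * run.sum(axis=-1, dtype=float)
    if normalize:
        k /= self_kernel(lx, config)
    return k


def wd_kernel(x, y, config: SvmConfig | None = None) -> float:
    """Unnormalised weighted-degree kernel between two peptides."""
    return float(kernel_matrix([x], [y], config, normalize=False)[0, 0])


def normalize_kernel(k_xy: float, k_xx: float, k_yy: float) -> float:
    """Cosine normalisation K^(x,y) = K(x,y) / sqrt(K(x,x) K(y,y))."""
    if k_xx <= 0 or k_yy <= 0:
        raise ValidationError("self-kernel values must be positive to normalise")
    return k_xy / float(np.sqrt(k_xx * k_yy))


@dataclass
class SvmModel:
    """Support peptides, dual coefficients (alpha_i * y_i) and bias."""

    support_sequences: list[str]
    dual_coef: np.ndarray
    intercept: float
    window_spec: WindowSpec
    config: SvmConfig

    @property
    def threshold(self) -> float:
        return self.config.threshold


def train_svm(dataset: LabelledDataset, config: SvmConfig | None = None) -> SvmModel:
    """Solve the soft-margin dual on the precomputed normalised kernel."""
    config = config or SvmConfig()
    labels = dataset.labels()
    if "POS" not in labels or "NEG" not in labels:
        raise ValidationError("training requires both POS and NEG examples")
    seqs = dataset.sequences()
    y = np.array([1 if lab == "POS" else 0 for lab in labels])
    gram = kernel_matrix(seqs, seqs, config)
    clf = SVC(C=config.c, kernel="precomputed")
    clf.fit(gram, y)
    if clf.fit_status_ != 0:
        raise ValidationError(
            f"SVM solver did not converge (libsvm status {clf.fit_status_})"
        )
    support = [seqs[i] for i in clf.support_]
    return SvmModel(
        support_sequences=support,
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        window_spec=dataset.window_spec,
        config=config,
    )


def score_many(model: SvmModel, peptides, block: int = 2048) -> np.ndarray:
    """Decision values f(p) = sum_i alpha_i y_i K^(x_i, p) + b for a batch."""
    if not model.support_sequences:
        raise ValidationError("empty SVM model: no support peptides")
    seqs = _seqs(peptides)
    if not seqs:
        return np.empty(0)
    want = model.window_spec.full_width
    if any(len(s) != want for s in seqs):
        raise ValidationError(
            f"peptide width mismatch: expected {want} for {model.window_spec}"
        )
    out = np.empty(len(seqs))
    for start in range(0, len(seqs), block):
        chunk = seqs[start : start + block]
        k = kernel_matrix(chunk, model.support_sequences, model.config)
        out[start : start + len(chunk)] = k @ model.dual_coef + model.intercept
    return out


def svm_score(model: SvmModel, peptide) -> float:
    """Decision value for one peptide window."""
    return float(score_many(model, [peptide])[0])


def svm_classify(model: SvmModel, peptide, threshold: float | None = None) -> bool:
    """Binding call: decision value >= threshold (default 0.25)."""
    t = model.threshold if threshold is None else threshold
    return svm_score(model, peptide) >= t


def save_svm(model: SvmModel, path, header_comment: str | None = None) -> None:
    payload = {
        "comment": header_comment or "",
        "window": [model.window_spec.left, model.window_spec.right],
        "config": asdict(model.config),
        "support_sequences": model.support_sequences,
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
    }
    Path(path).write_text(json.dumps(payload))


def load_svm(path) -> SvmModel:
    payload = json.loads(Path(path).read_text())
    cfg = dict(payload["config"])
    if cfg.get("weights") is not None:
        cfg["weights"] = tuple(cfg["weights"])
    return SvmModel(
        support_sequences=list(payload["support_sequences"]),
        dual_coef=np.array(payload["dual_coef"]),
        intercept=float(payload["intercept"]),
        window_spec=WindowSpec(*payload["window"]),
        config=SvmConfig(**cfg),
    )
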