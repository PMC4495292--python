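"""Classifier evaluation: confusion metrics, ROC/AUC, jackknife, bootstrap.

Metrics follow the standard confusion-matrix definitions

    SN  = TP / (TP + FN)                    (sensitivity / recall)
    SP  = TN / (TN + FP)                    (specificity)
    PPV = TP / (TP + FP)                    (precision)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any denominator factor vanishes.  The call
convention everywhere is "score >= threshold => positive".

Jackknife is leave-one-out cross-validation: train on n-1 examples, score
the held-out one, repeat, and feed the n out-of-sample scores to ROC/metric
computations.  AUC is the area under the ROC curve, equal to the normalised
Mann-Whitney statistic P(score_pos > score_neg) + 1/2 P(tie).

Bootstrap comparison of a method against the consensus resamples example
indices with replacement (paired), recomputes both MCCs at fixed thresholds
in each replicate, and reports the fraction of replicates in which the
method's MCC is at least the consensus MCC — a one-sided test of whether
the method fails to beat the consensus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .peptides import LabelledDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in (("tp", self.tp), ("fp", self.fp), ("tn", self.tn), ("fn", self.fn)):
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """SN/SP/PPV/ACC as fractions in [0, 1]; MCC in [-1, 1]."""

    sn: float
    sp: float
    ppv: float
    acc: float
    mcc: float

    def as_percent(self) -> dict[str, float]:
        """SN/SP/PPV/ACC in percent (1 dp convention) and MCC unchanged."""
        return {
            "SN": self.sn * 100.0,
            "SP": self.sp * 100.0,
            "PPV": self.ppv * 100.0,
            "ACC": self.acc * 100.0,
            "MCC": self.mcc,
        }


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Compute the five standard metrics from confusion counts."""
    if c.total == 0:
        raise ValidationError("all confusion counts are zero")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    ppv = tp / (tp + fp) if tp + fp > 0 else 0.0
    acc = (tp + tn) / c.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, ppv=ppv, acc=acc, mcc=mcc)


def _as_bool_labels(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab.upper() not in ("POS", "NEG"):
                raise ValidationError(f"unknown label {lab!r}")
            out.append(lab.upper() == "POS")
        else:
            out.append(bool(lab))
    return np.array(out, dtype=bool)


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts with the call rule score >= threshold => positive."""
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if scores.shape[0] != y.shape[0]:
        raise ValidationError(
            f"{scores.shape[0]} scores vs {y.shape[0]} labels"
        )
    calls = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(calls & y)),
        fp=int(np.sum(calls & ~y)),
        tn=int(np.sum(~calls & ~y)),
        fn=int(np.sum(~calls & y)),
    )


def _check_two_classes(y: np.ndarray) -> None:
    if y.all() or (~y).all():
        raise ValidationError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (normalised Mann-Whitney statistic)."""
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    _check_two_classes(y)
    return float(roc_auc_score(y, scores))


def roc_points(scores, labels) -> list[tuple[float, float, float]]:
    """(FPR, TPR, threshold) points of the ROC curve, for TSV export."""
    y = _as_bool_labels(labels)
    _check_two_classes(y)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def optimal_threshold(scores, labels) -> float:
    """The observed score that maximises accuracy (ties -> smallest score).

    Mirrors threshold selection from an accuracy/cut-off plot over the grid
    of observed scores, with the call rule score >= t.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    _check_two_classes(y)
    best_t, best_acc = None, -1.0
    for t in np.unique(scores):  # ascending, so ties keep the smallest t
        calls = scores >= t
        acc = float(np.mean(calls == y))
        if acc > best_acc:
            best_t, best_acc = float(t), acc
    if best_acc <= max(y.mean(), 1 - y.mean()):
        logger.warning(
            "optimal threshold accuracy %.3f does not beat the class prior",
            best_acc,
        )
    return best_t


def jackknife(
    dataset: LabelledDataset,
    train_fn: Callable[[LabelledDataset, int], object],
    score_fn: Callable[[object, object], float],
    seed: int = 0,
) -> np.ndarray:
    """Leave-one-out cross-validation scores, aligned with dataset order.

    ``train_fn(subset, fold_seed)`` builds a model on n-1 examples;
    ``score_fn(model, window)`` scores the held-out one.  The per-fold seed
    is derived deterministically from (seed, fold index) so stochastic
    trainers are reproducible.
    """
    n = len(dataset)
    if n < 3:
        raise ValidationError(f"jackknife needs at least 3 examples, got {n}")
    scores = np.empty(n)
    for i in range(n):
        sub = dataset.subset([j for j in range(n) if j != i])
        fold_seed = (seed * 1_000_003 + i) % (2**31)
        model = train_fn(sub, fold_seed)
        scores[i] = score_fn(model, dataset.windows[i])
    return scores


def bootstrap_mcc_pvalue(
    method_scores,
    consensus_scores,
    labels,
    method_threshold: float,
    consensus_threshold: float,
    n_reps: int = 100,
    seed: int = 0,
) -> float:
    """Paired bootstrap comparison of a method's MCC against the consensus.

    Each replicate resamples example indices with replacement and recomputes
    both MCCs at the supplied (fixed) thresholds.  Returns the fraction of
    replicates in which the method MCC >= consensus MCC; small values mean
    the method is significantly worse than the consensus.  Replicates that
    draw a single class are resampled (logged).
    """
    ms = np.asarray(method_scores, dtype=float)
    cs = np.asarray(consensus_scores, dtype=float)
    y = _as_bool_labels(labels)
    if not (ms.shape == cs.shape == y.shape):
        raise ValidationError("score and label vectors must be aligned")
    _check_two_classes(y)
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    wins = 0
    resampled = 0
    for _ in range(n_reps):
        for _attempt in range(1000):
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                break
            resampled += 1
        else:  # pragma: no cover - would need a pathological dataset
            raise ValidationError("could not draw a two-class bootstrap replicate")
        mcc_m = metrics_from_counts(
            confusion_at_threshold(ms[idx], y[idx], method_threshold)
        ).mcc
        mcc_c = metrics_from_counts(
            confusion_at_threshold(cs[idx], y[idx], consensus_threshold)
        ).mcc
        if mcc_m >= mcc_c:
            wins += 1
    if resampled:
        logger.info("bootstrap: redrew %d single-class replicate(s)", resampled)
    return wins / n_reps


def correlate_scores(a, b) -> float:
    """Pearson correlation coefficient between two aligned score vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("score vectors must be 1-D and aligned")
    if a.shape[0] < 3:
        raise ValidationError("need at least 3 points for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation is undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)
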