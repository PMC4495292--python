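"""Feed-forward neural network classifier with online backprop + momentum.

Peptide windows are sparsely encoded: each residue becomes a 20-long one-hot
vector in the fixed alphabet order (A, R, N, D, ...); padding/ambiguity 'X'
encodes as all zeros.  The network is a single hidden layer of sigmoid units
(default 20) feeding one sigmoid output, trained online (per-pattern weight
updates) by backpropagation with a momentum term:

    dw(t) = -eta * grad + mu * dw(t-1),   eta = 0.2, mu = 0.05 by default.

Targets are 1 for binders (POS) and 0 for non-binders (NEG); the default
decision threshold on the output is 0.55.

By default the full window including the central S/T is encoded, giving
20*(k+1) inputs; ``include_center=False`` switches to the 20*k flank-only
encoding.  Training exploits the sparsity of the one-hot input: only the
active input columns carry gradient, while the momentum term decays the
whole velocity every step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .peptides import (
    AA20,
    LabelledDataset,
    PeptideWindow,
    ValidationError,
    WindowSpec,
)

logger = logging.getLogger(__name__)

_AA20_INDEX = {aa: i for i, aa in enumerate(AA20)}

DEFAULT_ANN_THRESHOLD = 0.55


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class AnnConfig:
    """Hyperparameters of the backprop-with-momentum trainer."""

    learning_rate: float = 0.2
    momentum: float = 0.05
    hidden_units: int = 20
    epochs: int = 300
    seed: int = 0
    threshold: float = DEFAULT_ANN_THRESHOLD
    include_center: bool = True
    #: weight initialisation range: uniform in [-init_scale, +init_scale]
    init_scale: float = 0.3

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValidationError("momentum must be in [0, 1)")
        if self.hidden_units < 1:
            raise ValidationError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


def encode_residue(aa: str) -> np.ndarray:
    """One-hot encode a single residue (20-long); 'X'/unknown -> all zeros."""
    v = np.zeros(20)
    i = _AA20_INDEX.get(aa.upper())
    if i is not None:
        v[i] = 1.0
    return v


def _window_string(peptide, spec: WindowSpec, include_center: bool) -> str:
    s = peptide.sequence if isinstance(peptide, PeptideWindow) else str(peptide)
    if len(s) != spec.full_width:
        raise ValidationError(
            f"peptide {s!r} has width {len(s)}, expected {spec.full_width}"
        )
    if not include_center:
        s = s[: spec.left] + s[spec.left + 1 :]
    return s


def encode_binary(peptide, spec: WindowSpec, include_center: bool = True) -> np.ndarray:
    """Concatenated per-residue one-hot encoding of a window.

    Length is 20*(k+1) with the central residue included (default) or 20*k
    without it.
    """
    s = _window_string(peptide, spec, include_center)
    return np.concatenate([encode_residue(c) for c in s])


def _one_hot_indices(s: str) -> np.ndarray:
    """Flat indices of the 1-entries in the concatenated one-hot encoding."""
    return np.array(
        [p * 20 + _AA20_INDEX[c] for p, c in enumerate(s) if c in _AA20_INDEX],
        dtype=np.intp,
    )


@dataclass
class AnnModel:
    """Trained network weights plus the window spec and config that made them."""

    w_hidden: np.ndarray  # (hidden_units, n_inputs)
    b_hidden: np.ndarray  # (hidden_units,)
    w_out: np.ndarray  # (hidden_units,)
    b_out: float
    window_spec: WindowSpec
    config: AnnConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def threshold(self) -> float:
        return self.config.threshold


def train_ann(dataset: LabelledDataset, config: AnnConfig | None = None) -> AnnModel:
    """Train the network online over the dataset in input order.

    Deterministic given (dataset order, config, seed): weights start uniform
    in [-0.3, 0.3] from a seeded generator and the per-epoch pattern order
    is a seeded shuffle (online updates on class-blocked data would
    otherwise oscillate, with whole-class forgetting at the end of every
    epoch).  The summed squared error per epoch is recorded in
    ``loss_history`` and logged.
    """
    config = config or AnnConfig()
    spec = dataset.window_spec
    labels = dataset.labels()
    n_pos = labels.count("POS")
    n_neg = labels.count("NEG")
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("training requires both POS and NEG examples")
    if max(n_pos, n_neg) > 2 * min(n_pos, n_neg):
        logger.warning(
            "class imbalance %d POS vs %d NEG; near-balanced data recommended",
            n_pos, n_neg,
        )

    strings = [
        _window_string(w, spec, config.include_center) for w in dataset.windows
    ]
    n_in = 20 * len(strings[0])
    patterns = [_one_hot_indices(s) for s in strings]
    targets = np.array([1.0 if lab == "POS" else 0.0 for lab in labels])

    rng = np.random.default_rng(config.seed)
    a = config.init_scale
    w1 = rng.uniform(-a, a, (config.hidden_units, n_in))
    b1 = rng.uniform(-a, a, config.hidden_units)
    w2 = rng.uniform(-a, a, config.hidden_units)
    b2 = float(rng.uniform(-a, a))

    eta, mu = config.learning_rate, config.momentum
    v1 = np.zeros_like(w1)
    vb1 = np.zeros_like(b1)
    v2 = np.zeros_like(w2)
    vb2 = 0.0

    losses: list[float] = []
    order = np.arange(len(patterns))
    for epoch in range(config.epochs):
        sse = 0.0
        rng.shuffle(order)
        for j in order:
            idx, t = patterns[j], targets[j]
            h = _sigmoid(w1[:, idx].sum(axis=1) + b1)
            o = _sigmoid(float(w2 @ h) + b2)
            err = o - t
            sse += err * err
            delta_o = err * o * (1.0 - o)
            delta_h = delta_o * w2 * h * (1.0 - h)
            if mu > 0.0:
                v1 *= mu
                v1[:, idx] -= eta * delta_h[:, None]
                w1 += v1
                vb1 = mu * vb1 - eta * delta_h
                b1 += vb1
                v2 = mu * v2 - eta * delta_o * h
                w2 += v2
                vb2 = mu * vb2 - eta * delta_o
                b2 += vb2
            else:
                w1[:, idx] -= eta * delta_h[:, None]
                b1 -= eta * delta_h
                w2 -= eta * delta_o * h
                b2 -= eta * delta_o
        losses.append(sse)
    logger.info(
        "ANN training: %d epochs, SSE %.4f -> %.4f", config.epochs,
        losses[0], losses[-1],
    )
    return AnnModel(w1, b1, w2, b2, spec, config, losses)


def score_many(model: AnnModel, peptides) -> np.ndarray:
    """Vectorised network outputs in [0, 1] for a batch of windows."""
    cfg = model.config
    if isinstance(peptides, LabelledDataset):
        peptides = peptides.windows
    strings = [
        _window_string(p, model.window_spec, cfg.include_center) for p in peptides
    ]
    if not strings:
        return np.empty(0)
    x = np.zeros((len(strings), model.n_inputs))
    for r, s in enumerate(strings):
        x[r, _one_hot_indices(s)] = 1.0
    h = _sigmoid(x @ model.w_hidden.T + model.b_hidden)
    return _sigmoid(h @ model.w_out + model.b_out)


def ann_score(model: AnnModel, peptide) -> float:
    """Network output in [0, 1] for one window."""
    return float(score_many(model, [peptide])[0])


def ann_classify(model: AnnModel, peptide, threshold: float | None = None) -> bool:
    """Binding call: output >= threshold (default 0.55)."""
    t = model.threshold if threshold is None else threshold
    return ann_score(model, peptide) >= t


def save_ann(model: AnnModel, path, header_comment: str | None = None) -> None:
    payload = {
        "comment": header_comment or "",
        "window": [model.window_spec.left, model.window_spec.right],
        "config": asdict(model.config),
        "w_hidden": model.w_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "w_out": model.w_out.tolist(),
        "b_out": model.b_out,
        "loss_history": model.loss_history,
    }
    Path(path).write_text(json.dumps(payload))


def load_ann(path) -> AnnModel:
    payload = json.loads(Path(path).read_text())
    return AnnModel(
        np.array(payload["w_hidden"]),
        np.array(payload["b_hidden"]),
        np.array(payload["w_out"]),
        float(payload["b_out"]),
        WindowSpec(*payload["window"]),
        AnnConfig(**payload["config"]),
        list(payload.get("loss_history", [])),
    )
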