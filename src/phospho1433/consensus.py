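"""Consensus predictor: the arithmetic mean of the three method scores.

The ANN output lives in [0, 1], the PSSM score is unbounded and the SVM
decision value is unbounded; the consensus averages the raw scores without
rescaling.  The printed per-method cut-offs (0.55 / 0.80 / 0.25) and the
consensus cut-off (0.50) are mutually coherent only under raw averaging,
and top proteome-scan consensus scores of ~1.6-2.0 confirm an unbounded
component enters the mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import ann as ann_mod
from . import pssm as pssm_mod
from . import svm as svm_mod
from .peptides import PeptideWindow, ValidationError, WindowSpec

DEFAULT_CONSENSUS_THRESHOLD = 0.50


@dataclass(frozen=True)
class ConsensusConfig:
    threshold: float = DEFAULT_CONSENSUS_THRESHOLD

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValidationError("consensus threshold must be finite")


def consensus_score(ann: float, pssm: float, svm: float) -> float:
    """Arithmetic mean of the three raw method scores."""
    for name, v in (("ann", ann), ("pssm", pssm), ("svm", svm)):
        if not math.isfinite(v):
            raise ValidationError(f"{name} score is not finite: {v!r}")
    return (ann + pssm + svm) / 3.0


def consensus_classify(
    ann: float, pssm: float, svm: float, threshold: float = DEFAULT_CONSENSUS_THRESHOLD
) -> bool:
    return consensus_score(ann, pssm, svm) >= threshold


@dataclass(frozen=True)
class PredictionRecord:
    """All four scores and calls for one Ser/Thr site."""

    accession: str
    position: int
    residue: str
    motif: str
    ann: float
    pssm: float
    svm: float
    consensus: float
    ann_call: bool
    pssm_call: bool
    svm_call: bool
    consensus_call: bool


@dataclass
class ModelBundle:
    """The three trained models sharing one window spec, plus the consensus cut-off."""

    ann: ann_mod.AnnModel | None = None
    pssm: pssm_mod.PssmModel | None = None
    svm: svm_mod.SvmModel | None = None
    consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD

    def require_complete(self) -> None:
        for name in ("ann", "pssm", "svm"):
            if getattr(self, name) is None:
                raise ValidationError(f"model bundle is missing the {name} model")

    @property
    def window_spec(self) -> WindowSpec:
        self.require_complete()
        specs = {m.window_spec for m in (self.ann, self.pssm, self.svm)}
        if len(specs) != 1:
            raise ValidationError(
                f"models disagree on window spec: {sorted(map(str, specs))}"
            )
        return next(iter(specs))


def score_all_many(bundle: ModelBundle, peptides) -> dict[str, np.ndarray]:
    """Batch scores from all three models plus the consensus mean."""
    bundle.window_spec  # validates completeness + spec agreement
    a = ann_mod.score_many(bundle.ann, peptides)
    p = pssm_mod.score_many(bundle.pssm, peptides)
    s = svm_mod.score_many(bundle.svm, peptides)
    return {"ann": a, "pssm": p, "svm": s, "consensus": (a + p + s) / 3.0}


def predict_all(
    bundle: ModelBundle,
    peptide,
    accession: str = "peptide",
    position: int = 0,
) -> PredictionRecord:
    """Score one window with every method and apply the default cut-offs."""
    spec = bundle.window_spec
    motif = peptide.sequence if isinstance(peptide, PeptideWindow) else str(peptide)
    if len(motif) != spec.full_width:
        raise ValidationError(
            f"peptide {motif!r} has width {len(motif)}, expected {spec.full_width}"
        )
    if motif[spec.left] not in ("S", "T"):
        raise ValidationError(f"peptide {motif!r} is not centred on S/T")
    scores = score_all_many(bundle, [motif])
    a, p, s = (float(scores[k][0]) for k in ("ann", "pssm", "svm"))
    c = consensus_score(a, p, s)
    return PredictionRecord(
        accession=accession,
        position=position,
        residue=motif[spec.left],
        motif=motif,
        ann=a,
        pssm=p,
        svm=s,
        consensus=c,
        ann_call=a >= bundle.ann.threshold,
        pssm_call=p >= bundle.pssm.threshold,
        svm_call=s >= bundle.svm.threshold,
        consensus_call=c >= bundle.consensus_threshold,
    )


# ---------------------------------------------------------------------------
# model directory layout: pssm.txt, ann.json, svm.json, bundle.json

def save_models(bundle: ModelBundle, directory, header_comment: str | None = None) -> None:
    bundle.require_complete()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pssm_mod.save_pssm(bundle.pssm, directory / "pssm.txt", header_comment)
    ann_mod.save_ann(bundle.ann, directory / "ann.json", header_comment)
    svm_mod.save_svm(bundle.svm, directory / "svm.json", header_comment)
    (directory / "bundle.json").write_text(
        json.dumps(
            {
                "comment": header_comment or "",
                "consensus_threshold": bundle.consensus_threshold,
            }
        )
    )


def load_models(directory) -> ModelBundle:
    directory = Path(directory)
    for fname in ("pssm.txt", "ann.json", "svm.json"):
        if not (directory / fname).exists():
            raise ValidationError(f"{directory}: missing model file {fname}")
    threshold = DEFAULT_CONSENSUS_THRESHOLD
    meta = directory / "bundle.json"
    if meta.exists():
        threshold = float(json.loads(meta.read_text())["consensus_threshold"])
    return ModelBundle(
        ann=ann_mod.load_ann(directory / "ann.json"),
        pssm=pssm_mod.load_pssm(directory / "pssm.txt"),
        svm=svm_mod.load_svm(directory / "svm.json"),
        consensus_threshold=threshold,
    )
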