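"""Redundancy filtering for short peptides.

For peptides this short a single residue substitution can flip binding
specificity, so redundancy is defined combinatorially rather than by
percent identity: two windows of flank width k are redundant at threshold
``min_diff`` when they differ at fewer than ``min_diff`` positions.
Thresholds range from 1 (drop exact near-duplicates, <90% identity for
k = 10) up to floor(k/2) (50% identity).
"""

from __future__ import annotations

import logging

from .peptides import (
    LabelledDataset,
    PeptideWindow,
    ValidationError,
    WindowSpec,
    LABELS,
)

logger = logging.getLogger(__name__)


def _seq(p) -> str:
    return p.sequence if isinstance(p, PeptideWindow) else str(p)


def count_differences(p1, p2) -> int:
    """Number of positions at which two equal-width peptides differ.

    'X' is an ordinary symbol: padding vs. residue counts as a difference.
    """
    s1, s2 = _seq(p1), _seq(p2)
    if len(s1) != len(s2):
        raise ValidationError(
            f"cannot compare peptides of widths {len(s1)} and {len(s2)}"
        )
    return sum(c1 != c2 for c1, c2 in zip(s1, s2))


def redundancy_levels(spec: WindowSpec) -> list[int]:
    """All redundancy thresholds for a window: 1 .. floor(k/2), k = flank width."""
    return list(range(1, spec.width // 2 + 1))


def _check_threshold(min_diff: int, spec: WindowSpec) -> None:
    levels = redundancy_levels(spec)
    if min_diff not in levels:
        raise ValidationError(
            f"min_diff must be in 1..{spec.width // 2} for window {spec}, "
            f"got {min_diff}"
        )


def filter_redundant(dataset: LabelledDataset, min_diff: int) -> LabelledDataset:
    """Greedy keep-first redundancy filter, applied within each label class.

    Windows are visited in input order; a window is kept iff it differs at
    >= ``min_diff`` positions from every previously kept window of the same
    label.  Keep-first greediness is deliberate: reproducibility over
    optimality, since the choice of which member of a redundant pair to drop
    is otherwise arbitrary.
    """
    _check_threshold(min_diff, dataset.window_spec)
    kept_by_label: dict[str, list[str]] = {lab: [] for lab in LABELS}
    kept: list[PeptideWindow] = []
    for win in dataset.windows:
        prior = kept_by_label[win.label]
        if all(count_differences(win.sequence, q) >= min_diff for q in prior):
            prior.append(win.sequence)
            kept.append(win)
    return LabelledDataset(kept, dataset.window_spec)


def cross_class_duplicates(dataset: LabelledDataset) -> list[str]:
    """Report peptides that occur in both the POS and the NEG class.

    Cross-class duplicates are reported, never deleted: the filter operates
    within classes only.
    """
    pos = {w.sequence for w in dataset.windows if w.label == "POS"}
    neg = {w.sequence for w in dataset.windows if w.label == "NEG"}
    dupes = sorted(pos & neg)
    if dupes:
        logger.warning(
            "%d peptide(s) occur in both POS and NEG classes: %s",
            len(dupes),
            ", ".join(dupes[:5]) + ("..." if len(dupes) > 5 else ""),
        )
    return dupes
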