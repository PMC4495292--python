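"""Published blind-benchmark confusion counts for 14-3-3 site predictors.

Literature-reported confusion counts (TP, FP, TN, FN) for thirteen
predictors evaluated on a blind set of 38 experimentally verified
14-3-3-binding phosphosites and 32 non-binding sites.  The counts are
program input: the metric engine recomputes SN/SP/PPV/ACC/MCC from them,
which doubles as a regression check of the formulas against the printed
panel (percentages to 1 dp, MCC to 2 dp).
"""

from __future__ import annotations

from .evaluation import ConfusionCounts, MetricSet, metrics_from_counts

#: Reported confusion counts on the 38/32 blind set, keyed by predictor.
BLIND_CONFUSION: dict[str, ConfusionCounts] = {
    "Consensus": ConfusionCounts(28, 4, 28, 10),
    "ANN": ConfusionCounts(29, 5, 27, 9),
    "PSSM": ConfusionCounts(26, 3, 29, 12),
    "SVM": ConfusionCounts(27, 4, 28, 11),
    "Netphorest Scansite": ConfusionCounts(28, 7, 25, 10),
    "Scansite2 low": ConfusionCounts(28, 7, 25, 10),
    "ELM": ConfusionCounts(24, 4, 28, 14),
    "Scansite3 low": ConfusionCounts(27, 7, 25, 11),
    "Scansite3 minimum": ConfusionCounts(32, 13, 19, 6),
    "Scansite2 high": ConfusionCounts(12, 0, 32, 26),
    "Scansite2 medium": ConfusionCounts(17, 4, 28, 21),
    "Scansite3 high": ConfusionCounts(9, 0, 32, 29),
    "Scansite3 medium": ConfusionCounts(17, 4, 28, 21),
}

#: Published metric panel for the same rows: (SN%, SP%, PPV%, ACC%, MCC),
#: percentages printed to 1 dp and MCC to 2 dp.
BLIND_REPORTED: dict[str, tuple[float, float, float, float, float]] = {
    "Consensus": (73.7, 87.5, 87.5, 80.0, 0.61),
    "ANN": (76.3, 84.4, 85.3, 80.0, 0.60),
    "PSSM": (68.4, 90.6, 89.7, 78.6, 0.60),
    "SVM": (71.1, 87.5, 87.1, 78.6, 0.59),
    "Netphorest Scansite": (73.7, 78.1, 80.0, 75.7, 0.52),
    "Scansite2 low": (73.7, 78.1, 80.0, 75.7, 0.52),
    "ELM": (63.2, 87.5, 85.7, 74.3, 0.52),
    "Scansite3 low": (71.1, 78.1, 79.4, 74.3, 0.49),
    "Scansite3 minimum": (84.2, 59.4, 71.1, 72.9, 0.45),
    "Scansite2 high": (31.6, 100.0, 100.0, 62.9, 0.42),
    "Scansite2 medium": (44.7, 87.5, 81.0, 64.3, 0.35),
    "Scansite3 high": (23.7, 100.0, 100.0, 58.6, 0.35),
    "Scansite3 medium": (44.7, 87.5, 81.0, 64.3, 0.35),
}


def recompute_blind_metrics() -> dict[str, MetricSet]:
    """Metric panel recomputed from the stored confusion counts."""
    return {
        name: metrics_from_counts(counts)
        for name, counts in BLIND_CONFUSION.items()
    }
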