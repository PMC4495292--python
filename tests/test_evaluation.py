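"""Confusion metrics, ROC/AUC, threshold selection, jackknife, bootstrap."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phospho1433.evaluation import (
    ConfusionCounts,
    bootstrap_mcc_pvalue,
    confusion_at_threshold,
    correlate_scores,
    jackknife,
    metrics_from_counts,
    optimal_threshold,
    roc_auc,
    roc_points,
)
from phospho1433.peptides import (
    LabelledDataset,
    PeptideWindow,
    ValidationError,
    WindowSpec,
)


def brute_force_auc(scores, labels) -> float:
    """Mann-Whitney pair-counting oracle."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_blind_benchmark_rows(self):
        """Spot-check the metric formulas on published confusion rows."""
        m = metrics_from_counts(ConfusionCounts(29, 5, 27, 9)).as_percent()
        assert m["SN"] == pytest.approx(76.3, abs=0.05)
        assert m["ACC"] == pytest.approx(80.0, abs=0.05)
        assert m["MCC"] == pytest.approx(0.60, abs=0.005)
        m = metrics_from_counts(ConfusionCounts(28, 4, 28, 10)).as_percent()
        assert m["MCC"] == pytest.approx(0.61, abs=0.005)
        assert m["ACC"] == pytest.approx(80.0, abs=0.05)

    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionCounts(10, 0, 10, 0))
        assert (m.sn, m.sp, m.ppv, m.acc, m.mcc) == (1, 1, 1, 1, 1)

    def test_zero_denominator_mcc_is_zero(self):
        assert metrics_from_counts(ConfusionCounts(0, 0, 5, 5)).mcc == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            metrics_from_counts(ConfusionCounts(0, 0, 0, 0))

    @given(
        st.tuples(
            st.integers(0, 30), st.integers(0, 30),
            st.integers(0, 30), st.integers(0, 30),
        )
    )
    def test_mcc_antisymmetric_under_label_swap(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        mcc = metrics_from_counts(ConfusionCounts(tp, fp, tn, fn)).mcc
        swapped = metrics_from_counts(ConfusionCounts(fn, tn, fp, tp)).mcc
        assert mcc == pytest.approx(-swapped, abs=1e-12)


class TestConfusionAtThreshold:
    def test_call_rule_is_geq(self):
        c = confusion_at_threshold([0.9, 0.1], ["POS", "NEG"], 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)
        c = confusion_at_threshold([0.5], ["POS"], 0.5)
        assert c.tp == 1  # boundary counts as a positive call

    def test_infinite_threshold(self):
        c = confusion_at_threshold([0.9, 0.1], ["POS", "NEG"], np.inf)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            confusion_at_threshold([0.9], ["POS", "NEG"], 0.5)


class TestRocAuc:
    def test_separated_and_tied(self):
        assert roc_auc([1, 1, 0, 0], ["POS", "POS", "NEG", "NEG"]) == 1.0
        assert roc_auc([0.3, 0.3, 0.3, 0.3], ["POS", "POS", "NEG", "NEG"]) == 0.5

    def test_three_of_four_pairs(self):
        assert roc_auc(
            [0.9, 0.4, 0.6, 0.1], ["POS", "POS", "NEG", "NEG"]
        ) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.5, 0.6], ["POS", "POS"])

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.booleans()),
            min_size=4,
            max_size=12,
        )
    )
    def test_equals_mann_whitney_oracle(self, pairs):
        scores = [s / 5 for s, _ in pairs]
        labels = [l for _, l in pairs]
        if all(labels) or not any(labels):
            return
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_roc_points_span_the_curve(self):
        pts = roc_points([0.9, 0.4, 0.6, 0.1], ["POS", "POS", "NEG", "NEG"])
        fprs = [p[0] for p in pts]
        tprs = [p[1] for p in pts]
        assert min(fprs) == 0.0 and max(fprs) == 1.0
        assert max(tprs) == 1.0


class TestOptimalThreshold:
    def test_exhaustive_example(self):
        t = optimal_threshold([0.9, 0.8, 0.3, 0.7], ["POS", "POS", "NEG", "NEG"])
        assert t == pytest.approx(0.8)

    def test_tie_breaks_to_smallest(self):
        # thresholds 0.2 and 0.8 both give ACC 0.75; the smaller wins
        t = optimal_threshold(
            [0.8, 0.2, 0.5, 0.1], ["POS", "POS", "NEG", "NEG"]
        )
        assert t == pytest.approx(0.2)

    def test_degenerate_identical_scores(self):
        t = optimal_threshold([0.4, 0.4, 0.4], ["POS", "POS", "NEG"])
        assert t == pytest.approx(0.4)


class TestJackknife:
    def _tiny(self):
        return LabelledDataset(
            [
                PeptideWindow(s, label=l)
                for s, l in [
                    ("ASA", "POS"), ("RSR", "POS"), ("DSD", "NEG"),
                    ("ESE", "NEG"), ("GSG", "NEG"),
                ]
            ],
            WindowSpec(1, 1),
        )

    def test_constant_trainer(self):
        scores = jackknife(
            self._tiny(), lambda sub, s: None, lambda m, w: 0.7
        )
        assert (scores == 0.7).all()

    def test_each_fold_trains_on_n_minus_one(self):
        sizes = []
        jackknife(
            self._tiny(),
            lambda sub, s: sizes.append(len(sub)),
            lambda m, w: 0.0,
        )
        assert sizes == [4] * 5

    def test_too_small_rejected(self):
        ds = self._tiny().subset([0, 1])
        with pytest.raises(ValidationError):
            jackknife(ds, lambda sub, s: None, lambda m, w: 0.0)

    def test_fold_seeds_deterministic(self):
        seeds1, seeds2 = [], []
        for store in (seeds1, seeds2):
            jackknife(
                self._tiny(),
                lambda sub, s: store.append(s),
                lambda m, w: 0.0,
                seed=9,
            )
        assert seeds1 == seeds2
        assert len(set(seeds1)) == len(seeds1)


class TestBootstrap:
    LABELS = ["POS"] * 10 + ["NEG"] * 10

    def test_identical_methods_give_one(self):
        scores = np.linspace(1, 0, 20)
        p = bootstrap_mcc_pvalue(scores, scores, self.LABELS, 0.5, 0.5, seed=0)
        assert p == 1.0

    def test_inverted_method_gives_zero(self):
        perfect = np.array([1.0] * 10 + [0.0] * 10)
        inverted = 1.0 - perfect
        p = bootstrap_mcc_pvalue(
            inverted, perfect, self.LABELS, 0.5, 0.5, seed=0
        )
        assert p == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        method = rng.random(20)
        cons = rng.random(20)
        p1 = bootstrap_mcc_pvalue(method, cons, self.LABELS, 0.5, 0.5, seed=3)
        p2 = bootstrap_mcc_pvalue(method, cons, self.LABELS, 0.5, 0.5, seed=3)
        assert p1 == p2


class TestCorrelation:
    def test_perfect_and_inverse(self):
        assert correlate_scores([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert correlate_scores([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_closed_form_example(self):
        assert correlate_scores([1, 2, 3], [1, 2, 4]) == pytest.approx(
            0.9819805, abs=1e-6
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            correlate_scores([1, 1, 1], [1, 2, 3])
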