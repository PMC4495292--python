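"""Frequency matrices and the (POS-NEG)/BGD additive score."""

from __future__ import annotations

import numpy as np
import pytest

from phospho1433.peptides import (
    ALPHABET,
    LabelledDataset,
    PeptideWindow,
    ValidationError,
    WindowSpec,
)
from phospho1433.pssm import (
    FrequencyMatrix,
    PssmModel,
    build_frequency_matrix,
    load_pssm,
    pssm_classify,
    pssm_score,
    save_pssm,
    score_many,
    train_pssm,
    uniform_background,
)

SPEC11 = WindowSpec(1, 1)


def _bgd_ar(spec=SPEC11):
    """Background putting 1/2 on A and R at every column."""
    vals = np.zeros((21, spec.width))
    vals[ALPHABET.index("A")] = 0.5
    vals[ALPHABET.index("R")] = 0.5
    return FrequencyMatrix(vals, role="BGD")


@pytest.fixture
def toy_model():
    pos = build_frequency_matrix(["AR"], SPEC11, "POS", pseudocount=0.0)
    neg = build_frequency_matrix(["RA"], SPEC11, "NEG", pseudocount=0.0)
    return PssmModel(pos, neg, _bgd_ar(), SPEC11, threshold=0.8)


class TestBuildFrequencyMatrix:
    def test_single_peptide_indicator(self):
        m = build_frequency_matrix(["AR"], SPEC11, "POS", pseudocount=0.0)
        assert m.values[ALPHABET.index("A"), 0] == 1.0
        assert m.values[ALPHABET.index("R"), 1] == 1.0
        assert m.values.sum() == pytest.approx(2.0)

    def test_direct_counting(self):
        m = build_frequency_matrix(["AA", "AR"], SPEC11, "POS", pseudocount=0.0)
        assert m.values[ALPHABET.index("A"), 1] == pytest.approx(0.5)
        assert m.values[ALPHABET.index("R"), 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("pc", [0.0, 1.0, 0.25])
    def test_columns_normalised_after_smoothing(self, pc, small_dataset):
        m = build_frequency_matrix(
            small_dataset, small_dataset.window_spec, "POS", pseudocount=pc
        )
        assert np.allclose(m.values.sum(axis=0), 1.0)
        if pc > 0:
            assert (m.values > 0).all()

    def test_full_windows_drop_centre(self):
        # centre S must not be counted: the A flank columns carry everything
        m = build_frequency_matrix(["ASA"], SPEC11, "POS", pseudocount=0.0)
        assert m.k == 2
        assert m.values[ALPHABET.index("S")].sum() == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            build_frequency_matrix([], SPEC11, "POS")


class TestPssmScore:
    def test_hand_computed_toy(self, toy_model):
        # (1-0)/0.5 + (1-0)/0.5 on the matching peptide, mirrored on the other
        assert pssm_score(toy_model, "ASR") == pytest.approx(4.0, abs=1e-12)
        assert pssm_score(toy_model, "RSA") == pytest.approx(-4.0, abs=1e-12)

    def test_identical_pos_neg_gives_zero(self, small_dataset):
        spec = small_dataset.window_spec
        m = build_frequency_matrix(small_dataset, spec, "POS")
        model = PssmModel(
            m,
            FrequencyMatrix(m.values, "NEG", m.pseudocount),
            uniform_background(spec),
            spec,
        )
        scores = score_many(model, small_dataset)
        assert np.allclose(scores, 0.0)

    def test_swap_pos_neg_negates_scores(self, small_dataset, background_windows):
        spec = small_dataset.window_spec
        model = train_pssm(small_dataset, background=background_windows)
        swapped = PssmModel(
            FrequencyMatrix(model.neg.values, "POS", model.neg.pseudocount),
            FrequencyMatrix(model.pos.values, "NEG", model.pos.pseudocount),
            model.bgd,
            spec,
        )
        s1 = score_many(model, small_dataset)
        s2 = score_many(swapped, small_dataset)
        assert np.allclose(s1, -s2)

    def test_uniform_bgd_closed_form(self, small_dataset):
        """With BGD = 1/21 everywhere the score is 21 * sum(POS - NEG)."""
        spec = small_dataset.window_spec
        model = train_pssm(small_dataset, background=None)
        diff = model.pos.values - model.neg.values
        seqs = small_dataset.sequences()[:5]
        for s in seqs:
            flank = s[: spec.left] + s[spec.left + 1 :]
            expected = 21.0 * sum(
                diff[ALPHABET.index(c), j] for j, c in enumerate(flank)
            )
            assert pssm_score(model, s) == pytest.approx(expected, abs=1e-9)

    def test_zero_background_cell_instructs_pseudocount(self, toy_model):
        with pytest.raises(ValidationError, match="pseudocount"):
            pssm_score(toy_model, "CSC")  # C has zero BGD frequency

    def test_additive_over_columns(self, toy_model):
        assert pssm_score(toy_model, "ASA") + pssm_score(
            toy_model, "RSR"
        ) == pytest.approx(
            pssm_score(toy_model, "ASR") + pssm_score(toy_model, "RSA")
        )


class TestClassifyAndSerialize:
    @pytest.mark.parametrize(
        "score,threshold,call",
        [(0.80, 0.80, True), (0.79, 0.80, False), (0.79, 0.5, True)],
    )
    def test_threshold_boundary(self, toy_model, score, threshold, call):
        # scale the toy so its score on "ASR" equals the wanted value
        scale = score / 4.0
        pos = FrequencyMatrix(
            toy_model.pos.values * scale
            + (1 - scale) * uniform_background(SPEC11).values,
            "POS",
        )
        neg = FrequencyMatrix(
            toy_model.neg.values * scale
            + (1 - scale) * uniform_background(SPEC11).values,
            "NEG",
        )
        model = PssmModel(pos, neg, _bgd_ar(), SPEC11, threshold=threshold)
        assert pssm_score(model, "ASR") == pytest.approx(score)
        assert pssm_classify(model, "ASR") is call

    def test_round_trip(self, tmp_path, small_dataset, background_windows):
        model = train_pssm(small_dataset, background=background_windows)
        path = tmp_path / "pssm.txt"
        save_pssm(model, path, header_comment="demo")
        again = load_pssm(path)
        assert again.window_spec == model.window_spec
        assert again.threshold == model.threshold
        s1 = score_many(model, small_dataset)
        s2 = score_many(again, small_dataset)
        assert np.array_equal(s1, s2)
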