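"""Hinge scoring, LAC sets, Mondrian class-conditional calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conformap import (
    LacCalibration,
    calibrate_lac,
    calibrate_mondrian,
    hinge_scores,
    predict_set,
    predict_set_mondrian,
)


def one_vs_rest(p_true, n_classes=3, true_idx=0):
    """Probability matrix rows with a chosen true-class probability."""
    p_true = np.asarray(p_true, dtype=float)
    rest = (1.0 - p_true) / (n_classes - 1)
    out = np.tile(rest[:, None], (1, n_classes))
    out[:, true_idx] = p_true
    return out


class TestHingeScores:
    @pytest.mark.parametrize("p_true, expected", [(1.0, 0.0), (0.0, 1.0), (0.73, 0.27)])
    def test_one_minus_true_class_probability(self, p_true, expected):
        scores = hinge_scores(one_vs_rest([p_true]), [0])
        assert scores.values[0] == pytest.approx(expected)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="roster"):
            hinge_scores(one_vs_rest([0.5]), ["water"], classes=[0, 1, 2])

    def test_out_of_range_probabilities_rejected_not_clipped(self):
        with pytest.raises(ValueError, match="rejected"):
            hinge_scores(np.array([[1.2, 0.0]]), [0])

    def test_pseudo_probabilities_need_not_sum_to_one(self):
        # uncalibrated scores: rows summing over/under 1 are acceptable
        scores = hinge_scores(np.array([[0.9, 0.8, 0.7]]), [1])
        assert scores.values[0] == pytest.approx(0.2)


class TestLacCalibration:
    def test_hand_traced_threshold(self):
        # hinge scores {0.1, 0.2, 0.4, 0.6}; k = ceil(5 * 0.8) = 4 -> qhat 0.6
        probs = one_vs_rest([0.9, 0.8, 0.6, 0.4])
        cal = calibrate_lac(probs, [0, 0, 0, 0], alpha=0.2)
        assert cal.threshold(0.2) == pytest.approx(0.4)

    def test_perfectly_confident_calibration_gives_threshold_one(self):
        cal = calibrate_lac(one_vs_rest([1.0, 1.0, 1.0, 1.0]), [0] * 4, 0.5)
        assert cal.threshold(0.5) == pytest.approx(1.0)

    def test_alpha_grid_thresholds_non_decreasing(self, rng):
        # the published-thresholds pattern: 0.70..0.95 confidence in 5% steps
        p_true = rng.beta(5, 2, size=400)
        probs = one_vs_rest(p_true)
        alphas = [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
        cal = calibrate_lac(probs, np.zeros(400, dtype=int), alphas)
        ts = [cal.threshold(a) for a in alphas]
        assert len(ts) == 6
        assert all(t1 <= t2 for t1, t2 in zip(ts, ts[1:]))

    def test_uncalibrated_alpha_is_a_lookup_error(self):
        cal = calibrate_lac(one_vs_rest([0.9] * 9), [0] * 9, 0.1)
        with pytest.raises(KeyError, match="0.2"):
            cal.threshold(0.2)

    def test_dataframe_input_uses_column_roster(self):
        import pandas as pd

        frame = pd.DataFrame(one_vs_rest([0.9, 0.7]), columns=["a", "b", "c"])
        cal = calibrate_lac(frame, ["a", "a"], 0.4)
        assert cal.classes == ("a", "b", "c")


class TestPredictSet:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.15, {"A", "B"}), (0.75, set()), (0.0, {"A", "B", "C"})],
    )
    def test_threshold_rule_boundary_inclusive(self, t, expected):
        cal = LacCalibration(thresholds={0.1: t}, classes=("A", "B", "C"), n_cal=10)
        sets = predict_set(np.array([0.7, 0.2, 0.1]), cal, 0.1)
        assert sets.sets()[0] == frozenset(expected)

    def test_boundary_equality_included(self):
        cal = LacCalibration(thresholds={0.1: 0.2}, classes=("A", "B", "C"), n_cal=10)
        sets = predict_set(np.array([0.7, 0.2, 0.1]), cal, 0.1)
        assert "B" in sets.sets()[0]

    def test_empty_sets_are_retained(self):
        cal = LacCalibration(thresholds={0.1: 0.99}, classes=("A", "B"), n_cal=10)
        sets = predict_set(np.array([[0.5, 0.4], [0.995, 0.0]]), cal, 0.1)
        assert sets.cardinality.tolist() == [0, 1]

    @given(seed=st.integers(0, 500))
    def test_sets_nest_across_alpha(self, seed):
        # lower tolerance (higher confidence) can only grow the set
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(5), size=300)
        labels = rng.integers(0, 5, size=300)
        alphas = [0.02, 0.05, 0.1, 0.2, 0.3]
        cal = calibrate_lac(probs[:200], labels[:200], alphas)
        prev = None
        for a in alphas:  # increasing alpha -> shrinking sets
            member = predict_set(probs[200:], cal, a).membership
            if prev is not None:
                assert np.all(member <= prev)
            prev = member

    def test_cardinality_bounds(self, rng):
        probs = rng.dirichlet(np.ones(4), size=100)
        cal = LacCalibration(thresholds={0.1: 0.0}, classes=(0, 1, 2, 3), n_cal=10)
        sets = predict_set(probs, cal, 0.1)
        assert np.all(sets.cardinality == 4)

    def test_membership_frame_export(self):
        cal = LacCalibration(thresholds={0.1: 0.5}, classes=("A", "B"), n_cal=5)
        frame = predict_set(np.array([[0.9, 0.1]]), cal, 0.1).to_frame()
        assert frame.loc[0, "A"] == 1
        assert frame.loc[0, "B"] == 0
        assert frame.loc[0, "set_size"] == 1


class TestMondrian:
    def test_single_stratum_equals_marginal_lac(self, rng):
        p_true = rng.beta(5, 2, size=200)
        probs = p_true[:, None]  # one-class roster
        labels = np.zeros(200, dtype=int)
        lac = calibrate_lac(probs, labels, 0.1)
        mon = calibrate_mondrian(probs, labels, 0.1)
        assert mon.thresholds[0] == pytest.approx(lac.threshold(0.1))

    def test_matched_class_score_distributions_give_close_thresholds(self):
        rng = np.random.default_rng(0)
        n = 4000
        p_true = rng.beta(8, 2, size=n)
        labels = np.repeat([0, 1], n // 2)
        probs = np.empty((n, 2))
        probs[np.arange(n), labels] = p_true
        probs[np.arange(n), 1 - labels] = 1 - p_true
        mon = calibrate_mondrian(probs, labels, 0.1)
        assert mon.thresholds[0] == pytest.approx(mon.thresholds[1], abs=0.03)

    def test_zero_instance_class_raises_naming_it(self):
        probs = np.array([[0.9, 0.05, 0.05]] * 30)
        with pytest.raises(ValueError, match="2"):
            calibrate_mondrian(probs, [0, 1] * 15, 0.1)

    def test_small_stratum_flagged_with_always_include_threshold(self):
        rng = np.random.default_rng(1)
        labels = np.array([0] * 100 + [1] * 3)
        probs = rng.dirichlet(np.ones(2), size=103)
        mon = calibrate_mondrian(probs, labels, 0.05)
        assert 1 in mon.flagged
        assert mon.thresholds[1] == 0.0  # class 1 always included: still valid

    @pytest.mark.parametrize(
        "t_a, t_b, expected",
        [(0.5, 0.45, {"A"}), (0.7, 0.3, {"B"}), (0.0, 0.0, {"A", "B"})],
    )
    def test_per_class_threshold_rule(self, t_a, t_b, expected):
        from conformap import MondrianCalibration

        mon = MondrianCalibration(
            thresholds={"A": t_a, "B": t_b},
            n_cal_per_class={"A": 50, "B": 50},
            alpha=0.1,
            classes=("A", "B"),
        )
        sets = predict_set_mondrian(np.array([0.6, 0.4]), mon)
        assert sets.sets()[0] == frozenset(expected)
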