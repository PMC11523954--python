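"""Kaplan–Meier, log-rank, Harrell's C, and quartile × response tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pwlscore import (
    InvalidParameterError,
    UndefinedTestError,
    harrell_c,
    km_estimate,
    logrank_test,
    quartile_response_table,
)
from conftest import brute_force_c


def _two_group_logrank_by_hand(time, event, group):
    """Textbook observed-minus-expected two-group statistic."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    o1 = e1 = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o1 - e1) ** 2 / v


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curves = km_estimate([5, 10, 15], [0, 0, 0])
        assert (curves["all"]["survival"] == 1.0).all()

    def test_product_limit_by_hand(self):
        # n = 4, events at days 2 and 4, censoring after day 4
        curves = km_estimate([2, 4, 5, 6], [1, 1, 0, 0])
        s = curves["all"].set_index("time")["survival"]
        assert s.loc[2.0] == pytest.approx(0.75)
        assert s.loc[4.0] == pytest.approx(0.5)

    def test_post_event_censor_time_does_not_move_curve(self):
        # a censoring after the last event never enters a risk-set ratio
        near = km_estimate([2, 4, 5], [1, 1, 0])["all"].set_index("time")["survival"]
        far = km_estimate([2, 4, 9], [1, 1, 0])["all"].set_index("time")["survival"]
        for t in (2.0, 4.0):
            assert near.loc[t] == pytest.approx(far.loc[t], abs=1e-12)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 30, 40).astype(float)
        curves = km_estimate(times, np.ones(40, dtype=int))
        tab = curves["all"]
        for t, s in zip(tab["time"], tab["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_curve_monotone_non_increasing_from_one(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        tab = km_estimate(t, e)["all"]
        assert tab["survival"].iloc[0] == 1.0
        assert (np.diff(tab["survival"]) <= 1e-12).all()

    def test_grouped_curves_and_empty_group_error(self):
        curves = km_estimate([1, 2, 3, 4], [1, 1, 1, 1], ["a", "a", "b", "b"])
        assert set(curves) == {"a", "b"}


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = [3, 5, 7, 9]
        e = [1, 1, 0, 1]
        res = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)
        assert res.df == 1

    def test_matches_hand_computed_six_sample_table(self):
        time = [1, 2, 3, 4, 5, 6]
        event = [1, 1, 0, 1, 1, 0]
        group = [0, 1, 0, 1, 0, 1]
        expected = _two_group_logrank_by_hand(time, event, group)
        res = logrank_test(time, event, group)
        assert res.statistic == pytest.approx(expected, abs=1e-6)

    def test_matches_hand_computation_on_random_data(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = 20
            time = rng.integers(1, 15, n).astype(float)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                continue
            group = rng.integers(0, 2, n)
            if len(np.unique(group)) < 2:
                continue
            expected = _two_group_logrank_by_hand(time, event, group)
            assert logrank_test(time, event, group).statistic == pytest.approx(
                expected, abs=1e-6
            )

    def test_all_censored_undefined(self):
        with pytest.raises(UndefinedTestError):
            logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])

    def test_single_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_label_shuffling_gives_chi_square_mean(self):
        # under exchangeability the statistic averages ≈ df across shuffles
        rng = np.random.default_rng(3)
        time = rng.exponential(10, 40)
        event = np.ones(40, dtype=int)
        stats_ = []
        for _ in range(200):
            g = rng.permutation(np.repeat([0, 1], 20))
            stats_.append(logrank_test(time, event, g).statistic)
        assert np.mean(stats_) == pytest.approx(1.0, abs=0.35)


class TestHarrellC:
    def test_all_tied_scores_give_half(self):
        assert harrell_c([1, 2, 3, 4], [1, 1, 1, 1], [5, 5, 5, 5]) == 0.5

    def test_perfect_ordering_gives_one(self):
        # higher score = better prognosis = longer time
        assert harrell_c([1, 2, 3], [1, 1, 1], [0.1, 0.5, 0.9]) == 1.0

    def test_risk_orientation_flips(self):
        c_good = harrell_c([1, 2, 3], [1, 1, 1], [0.9, 0.5, 0.1])
        assert c_good == 0.0
        c_risk = harrell_c(
            [1, 2, 3], [1, 1, 1], [0.9, 0.5, 0.1], higher_score_better_prognosis=False
        )
        assert c_risk == 1.0

    def test_matches_exhaustive_enumeration_with_censoring(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            n = int(rng.integers(5, 20))
            time = rng.integers(1, 10, n).astype(float)
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                continue
            score = np.round(rng.random(n), 1)
            expected = brute_force_c(time, event, score)
            if np.isnan(expected):
                continue
            assert harrell_c(time, event, score) == pytest.approx(
                expected, abs=1e-12
            )

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        time = rng.exponential(5, 30)
        event = rng.integers(0, 2, 30)
        event[0] = 1
        score = rng.standard_normal(30)
        a = harrell_c(time, event, score)
        b = harrell_c(time, event, np.exp(2 * score) + 3)
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_censored_undefined(self):
        with pytest.raises(UndefinedTestError):
            harrell_c([1, 2, 3], [0, 0, 0], [1, 2, 3])


class TestQuartileResponse:
    def test_identical_distribution_gives_null_statistic(self):
        groups = np.repeat(["Q1", "Q2", "Q3", "Q4"], 10)
        resp = np.tile([0, 1], 20)
        res = quartile_response_table(groups, resp)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.df == 3

    def test_printed_style_correct_fractions(self):
        # 27 per group; 21 non-responders correct in Q1, 16 responders in Q4
        groups = np.repeat(["Q1", "Q2", "Q3", "Q4"], 27)
        resp = np.concatenate(
            [
                np.array([0] * 21 + [1] * 6),
                np.array([0] * 14 + [1] * 13),
                np.array([0] * 12 + [1] * 15),
                np.array([0] * 11 + [1] * 16),
            ]
        )
        res = quartile_response_table(groups, resp)
        assert res.correct_fractions["Q1"] == pytest.approx(21 / 27)
        assert res.correct_fractions["Q4"] == pytest.approx(16 / 27)
        assert res.q1_vs_q4 is not None

    def test_two_by_two_collapse_matches_textbook_formula(self):
        groups = np.repeat(["Q1", "Q4"], 20)
        resp = np.array([0] * 15 + [1] * 5 + [0] * 6 + [1] * 14)
        res = quartile_response_table(groups, resp)
        a, b, c, d = 15, 5, 6, 14
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expected, abs=1e-9)
        assert res.df == 1

    def test_low_expected_cells_flagged_not_fatal(self):
        groups = np.array(["Q1"] * 3 + ["Q2"] * 3)
        resp = np.array([0, 0, 1, 0, 1, 1])
        res = quartile_response_table(groups, resp)
        assert isinstance(res.low_expected_warning, bool)
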