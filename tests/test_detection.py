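"""The three gain criteria, reversal rule, selection and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import suddengain as sg
from suddengain.detection import GainWindow, _round_half_away

from .oracle import brute_force_gains, random_short_trajectory, t_quantile


class TestCriterion1:
    @pytest.mark.parametrize("pre,post,expected", [
        (60, 40, True),     # the canonical 20-point drop
        (60, 49, False),    # 11 points, below the cutoff
        (60, 48, True),     # exactly 12: inclusive boundary
    ])
    def test_cutoff_boundary(self, pre, post, expected):
        assert sg.check_criterion1(pre, post, cutoff=12) is expected


class TestCriterion2:
    @pytest.mark.parametrize("pre,post,expected", [
        (60, 40, True),     # 20 >= 15
        (60, 45, True),     # exactly 25%: inclusive
        (100, 80, False),   # 20 < 25
    ])
    def test_quarter_of_pregain(self, pre, post, expected):
        assert sg.check_criterion2(pre, post, pct=0.25) is expected

    def test_zero_pregain_score_cannot_gain(self):
        assert sg.check_criterion2(0, 0) is False


class TestCriterion3:
    def test_full_window_critical_value_is_278(self):
        assert sg.critical_value(3, 3) == pytest.approx(2.776, abs=5e-4)

    @pytest.mark.parametrize("n_pre,n_post", [(3, 3), (2, 3), (3, 2), (2, 2)])
    def test_matches_independent_t_inversion(self, n_pre, n_post):
        independent = t_quantile(0.975, n_pre + n_post - 2)
        assert sg.critical_value(n_pre, n_post) == pytest.approx(independent, rel=1e-9)

    def test_more_missing_means_more_stringent(self):
        assert sg.critical_value(2, 3) > sg.critical_value(3, 3)
        assert sg.critical_value(2, 2) > sg.critical_value(2, 3)

    def test_window_counts_below_two_rejected(self):
        with pytest.raises(ValueError):
            sg.critical_value(1, 3)

    def test_zero_variance_passes_on_any_positive_difference(self):
        window = GainWindow(n=4, pre_values=(60, 60, 60), post_values=(40, 40, 40))
        assert sg.check_criterion3(window) is True

    def test_fluctuating_window_fails(self):
        # diff 13.33 vs 2.776 * 5.7735 = 16.03
        window = GainWindow(n=4, pre_values=(60, 50, 60), post_values=(40, 50, 40))
        assert sg.check_criterion3(window) is False

    def test_missing_value_uses_adjusted_critical_value(self):
        # (2,3) window, zero variance: 3.182 * 0 = 0 < 20
        window = GainWindow(n=4, pre_values=(60, 60), post_values=(40, 40, 40))
        assert sg.check_criterion3(window) is True


class TestEnumerate:
    def test_full_series_candidates_span_2_to_12(self):
        series = {w: 80.0 for w in range(1, 15)}
        ns = [w.n for w in sg.enumerate_candidates(series)]
        assert ns == list(range(2, 13))

    def test_missing_week_blocks_adjacent_intervals(self):
        series = {w: 80.0 for w in range(1, 15) if w != 5}
        ns = [w.n for w in sg.enumerate_candidates(series)]
        assert 4 not in ns and 5 not in ns

    def test_two_observed_weeks_yield_nothing(self):
        assert sg.enumerate_candidates({1: 80.0, 2: 60.0}) == []


class TestReversal:
    def test_half_loss_is_inclusive(self):
        assert sg.detect_reversal(40, 20, {10: 50.0}) == (True, 10)

    def test_just_below_threshold_is_not_reversed(self):
        assert sg.detect_reversal(40, 20, {10: 49.0}) == (False, None)

    def test_no_subsequent_observations(self):
        assert sg.detect_reversal(40, 20, {}) == (False, None)

    def test_first_qualifying_week_reported(self):
        rev, week = sg.detect_reversal(40, 20, {8: 45.0, 9: 52.0, 11: 60.0})
        assert (rev, week) == (True, 9)


class TestDetectGains:
    def test_constant_trajectory_has_no_gains(self):
        assert sg.detect_gains({w: 80.0 for w in range(1, 15)}) == []

    def test_worked_example_embedded(self):
        series = dict(enumerate(
            [80, 75, 70, 60, 60, 60, 40, 40, 40, 38, 36, 35, 33, 30], start=1))
        gains = sg.detect_gains({k: float(v) for k, v in series.items()})
        assert len(gains) == 1
        g = gains[0]
        assert (g.n, g.score_n, g.score_n1, g.magnitude) == (6, 60, 40, 20)
        assert not g.reversed

    def test_primary_gain_prefers_magnitude_then_earliest(self):
        mk = lambda n, mag: sg.SuddenGain("p", n, 60, 60 - mag, mag)
        assert sg.select_primary_gain([mk(4, 15), mk(9, 25)]).n == 9
        assert sg.select_primary_gain([mk(3, 20), mk(8, 20)]).n == 3
        only = mk(5, 18)
        assert sg.select_primary_gain([only]) is only
        assert sg.select_primary_gain([]) is None

    @given(data=st.data())
    @settings(max_examples=300, deadline=None)
    def test_oracle_equivalence_on_random_trajectories(self, data):
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        series = random_short_trajectory(rng)
        expected = brute_force_gains(series)
        got = [g.n for g in sg.detect_gains(series)]
        assert got == expected

    @given(data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_raising_thresholds_never_adds_gains(self, data):
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        series = random_short_trajectory(rng)
        base = len(sg.detect_gains(series, sg.GainCriteria()))
        stricter_cut = len(sg.detect_gains(series, sg.GainCriteria(cutoff=20)))
        stricter_pct = len(sg.detect_gains(series, sg.GainCriteria(pct=0.4)))
        assert stricter_cut <= base
        assert stricter_pct <= base


class TestSummaries:
    def test_counts_and_rate(self, fixture_gains, fixture_cohort):
        summary = sg.summarize_cohort(fixture_gains, fixture_cohort.cohort)
        assert summary.n_gains_total == sum(
            k * v for k, v in summary.gains_per_participant.items())
        assert summary.n_with_gain <= summary.n_participants
        assert 0 <= summary.occurrence_rate_pct <= 100

    def test_zero_gain_summary(self, small_cohort):
        empty = sg.detect_cohort(small_cohort.subset(["B"]))
        summary = sg.summarize_cohort(empty, small_cohort.subset(["B"]))
        assert summary.n_gains_total == 0
        assert summary.occurrence_rate_pct == 0
        assert summary.pre_gain_week_histogram == {}

    def test_rounding_half_away_from_zero(self):
        assert _round_half_away(38.5) == 39
        assert _round_half_away(39.4) == 39


class TestCompareDuration:
    def test_separated_groups_have_extreme_u(self):
        res = sg.compare_duration([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0

    def test_identical_groups_not_significant(self):
        res = sg.compare_duration([8, 10, 12, 14], [8, 10, 12, 14])
        assert res["p"] == pytest.approx(1.0, abs=0.05)

    def test_empty_group_named_in_error(self):
        with pytest.raises(ValueError, match="no-gain group"):
            sg.compare_duration([1, 2], [])

    def test_type_one_error_rate_near_nominal(self, rng):
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(14, 3, size=30)
            y = rng.normal(14, 3, size=40)
            if sg.compare_duration(x, y)["p"] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07
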