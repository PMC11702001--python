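"""Outcome and process mixed models: recovery, contrasts, effect sizes."""

import numpy as np
import pandas as pd
import pytest

import suddengain as sg
from suddengain.models import ModelError


def simulate_endpoints(rng, n=146, diff_post=25.0, diff_fu=20.0,
                       resid_sd=15.0, intercept_sd=8.0):
    """Two-timepoint endpoint data with a known group difference."""
    rows = []
    for i in range(n):
        has_gain = i < n // 2
        base = rng.normal(83, 20)
        b = rng.normal(0, intercept_sd)
        post = base - 40 - diff_post * has_gain + b + rng.normal(0, resid_sd)
        fu = base - 45 - diff_fu * has_gain + b + rng.normal(0, resid_sd)
        rows.append({"participant_id": f"p{i}", "time": "post", "lsas": post,
                     "sg": has_gain, "baseline_lsas": base})
        rows.append({"participant_id": f"p{i}", "time": "followup", "lsas": fu,
                     "sg": has_gain, "baseline_lsas": base})
    return pd.DataFrame(rows)


class TestOutcomeModel:
    def test_noiseless_difference_recovered_exactly(self):
        df = simulate_endpoints(np.random.default_rng(0), n=40, diff_post=10,
                                diff_fu=10, resid_sd=0.0, intercept_sd=0.0)
        res = sg.fit_outcome_model(df)
        assert res.differences.set_index("time")["estimate"]["post"] == pytest.approx(10.0)
        assert res.differences.set_index("time")["estimate"]["followup"] == pytest.approx(10.0)

    def test_single_group_is_an_error(self):
        df = simulate_endpoints(np.random.default_rng(0), n=10)
        df["sg"] = True
        with pytest.raises(ModelError, match="one gain-status group"):
            sg.fit_outcome_model(df)

    def test_estimate_unbiased_on_moderate_replicates(self, rng):
        ests = []
        for _ in range(40):
            res = sg.fit_outcome_model(simulate_endpoints(rng))
            ests.append(res.differences.set_index("time")["estimate"]["post"])
        # SE per replicate ~ 2.9 -> MC error of the mean ~ 0.46
        assert np.mean(ests) == pytest.approx(25.0, abs=1.5)

    def test_cell_stats_are_raw_descriptives(self, rng):
        df = simulate_endpoints(rng)
        res = sg.fit_outcome_model(df)
        cell = res.cell_stats.set_index(["sg", "time"])
        raw = df[(df["sg"]) & (df["time"] == "post")]["lsas"]
        assert cell.loc[(True, "post"), "mean"] == pytest.approx(raw.mean())
        assert cell.loc[(True, "post"), "sd"] == pytest.approx(raw.std(ddof=1))


class TestProcessModel:
    def test_permuting_participants_leaves_estimates_unchanged(self, rng):
        df = sg.simulate_around_gain(sg.SimConfig(), sg.SCQ_FREQUENCY, 57, rng)
        fit_a = sg.fit_process_model(df, sg.SCQ_FREQUENCY)
        fit_b = sg.fit_process_model(df.sample(frac=1.0, random_state=3),
                                     sg.SCQ_FREQUENCY)
        a = sg.consecutive_contrasts(fit_a)["estimate"]
        b = sg.consecutive_contrasts(fit_b)["estimate"]
        assert np.allclose(a, b)

    def test_too_few_timepoints_error_names_measure(self):
        df = pd.DataFrame({
            "participant_id": ["p1", "p2"],
            "measure": ["phq9", "phq9"],
            "timepoint": ["n", "n"],
            "value": [5.0, 6.0],
        })
        with pytest.raises(ModelError, match="phq9"):
            sg.fit_process_model(df, "phq9")

    def test_step_drop_recovered_at_gain_interval(self, rng):
        """A drop injected only at n->n+1 shows up in that contrast alone."""
        ests = np.zeros(5)
        reps = 20
        for _ in range(reps):
            df = sg.simulate_around_gain(sg.SimConfig(), sg.SCQ_BELIEF, 57, rng)
            fit = sg.fit_process_model(df, sg.SCQ_BELIEF)
            ests += sg.consecutive_contrasts(fit)["estimate"].to_numpy()
        ests /= reps
        # injected drop is 194.65 at the gain interval; slope ~12/week elsewhere
        assert ests[2] == pytest.approx(-194.65 - 12.0, abs=15.0)
        assert np.all(np.abs(ests[[0, 1, 3, 4]] + 12.0) < 15.0)

    def test_contrasts_telescope_to_end_minus_start(self, rng):
        df = sg.simulate_around_gain(sg.SimConfig(), sg.SCQ_FREQUENCY, 57, rng)
        fit = sg.fit_process_model(df, sg.SCQ_FREQUENCY)
        table = sg.consecutive_contrasts(fit)
        total = table["estimate"].sum()
        means = fit.marginal_means
        assert total == pytest.approx(means["n+3"] - means["n-2"], abs=1e-8)


class TestBonferroniAndD:
    def test_adjusted_p_capped_and_ordered(self, rng):
        df = sg.simulate_around_gain(sg.SimConfig(), sg.PHQ9, 57, rng)
        fit = sg.fit_process_model(df, sg.PHQ9)
        table = sg.consecutive_contrasts(fit)
        assert (table["p_adj"] >= table["p"] - 1e-12).all()
        assert (table["p_adj"] <= 1.0).all()

    def test_adjustment_factor_is_five(self):
        assert min(1.0, 5 * 0.0002) == pytest.approx(0.001)
        assert min(1.0, 5 * 0.30) == 1.0

    def test_cohens_d_basic_values(self):
        assert sg.cohens_d(10.0, 10.0) == 1.0
        assert sg.cohens_d(0.0, 7.3) == 0.0
        assert np.isnan(sg.cohens_d(5.0, 0.0))

    def test_d_from_printed_cells(self):
        """Raw-score d computed from two cells' means and SDs by hand."""
        n1 = n2 = 57
        mean1, sd1, mean2, sd2 = 20.00, 13.24, 48.75, 26.06
        pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
        d = sg.cohens_d(mean2 - mean1, pooled)
        assert d == pytest.approx(abs(mean2 - mean1) / pooled)
        assert d == pytest.approx(1.391, abs=1e-3)
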