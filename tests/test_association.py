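"""Correlations, the HV age prediction band, abnormality calls, group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from swaymetrics.association import (
    AgeReferenceBand,
    call_abnormal,
    compare_groups,
    correlate,
    subject_values,
)
from swaymetrics.panel import BiomarkerPanel


def panel_from_matrix(values: pd.DataFrame) -> BiomarkerPanel:
    idx = pd.MultiIndex.from_product(
        [values.index, ["T1"]], names=["subject_id", "trial_id"]
    )
    v = pd.DataFrame(values.to_numpy(), index=idx, columns=values.columns)
    flags = pd.DataFrame("ok", index=idx, columns=values.columns)
    return BiomarkerPanel(values=v, flags=flags, kind="synthetic")


def make_cohort(n, rng, diagnosis="HV"):
    return pd.DataFrame(
        {
            "age": rng.uniform(20, 70, n),
            "sex": rng.choice(["M", "F"], n),
            "diagnosis": diagnosis,
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id"),
    )


class TestSubjectValues:
    def test_mean_over_non_outlier_trials(self):
        idx = pd.MultiIndex.from_tuples(
            [("A", "T1"), ("A", "T2"), ("B", "T1")], names=["subject_id", "trial_id"]
        )
        values = pd.DataFrame({"b": [1.0, 3.0, 5.0]}, index=idx)
        flags = pd.DataFrame({"b": ["ok", "outlier", "ok"]}, index=idx)
        subj = subject_values(BiomarkerPanel(values=values, flags=flags))
        assert subj.loc["A", "b"] == 1.0  # outlier trial excluded
        assert subj.loc["B", "b"] == 5.0


class TestCorrelate:
    def test_exact_linear_outcome_gives_r_one(self, rng):
        n = 30
        cohort = make_cohort(n, rng)
        x = rng.standard_normal(n)
        cohort["CombiWISE"] = 3.0 * x + 1.0
        panel = panel_from_matrix(pd.DataFrame({"b": x}, index=cohort.index))
        rep = correlate(panel, cohort, ["CombiWISE"], strata=["all"])
        assert rep["r"].iloc[0] == pytest.approx(1.0)

    def test_negating_biomarker_negates_r(self, rng):
        n = 40
        cohort = make_cohort(n, rng)
        x = rng.standard_normal(n)
        cohort["CombiWISE"] = 2 * x + rng.standard_normal(n)
        rep_pos = correlate(
            panel_from_matrix(pd.DataFrame({"b": x}, index=cohort.index)),
            cohort, ["CombiWISE"], strata=["all"],
        )
        rep_neg = correlate(
            panel_from_matrix(pd.DataFrame({"b": -x}, index=cohort.index)),
            cohort, ["CombiWISE"], strata=["all"],
        )
        assert rep_neg["r"].iloc[0] == pytest.approx(-rep_pos["r"].iloc[0])

    def test_designed_correlation_recovered(self):
        # biomarker and outcome share a latent factor with rho = 0.6
        rho, n = 0.6, 150
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            cohort = make_cohort(n, rng)
            latent = rng.standard_normal(n)
            x = latent
            y = rho * latent + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            cohort["CombiWISE"] = y
            panel = panel_from_matrix(pd.DataFrame({"b": x}, index=cohort.index))
            rep = correlate(panel, cohort, ["CombiWISE"], strata=["all"])
            estimates.append(rep["r"].iloc[0])
        assert np.all(np.abs(np.asarray(estimates) - rho) < 0.15)

    def test_permuted_outcome_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            n = 100
            cohort = make_cohort(n, rng)
            x = rng.standard_normal(n)
            cohort["CombiWISE"] = rng.permutation(3 * x)  # association destroyed
            panel = panel_from_matrix(pd.DataFrame({"b": x}, index=cohort.index))
            rep = correlate(panel, cohort, ["CombiWISE"], strata=["all"])
            if rep["q_value"].iloc[0] <= 0.05:
                hits += 1
        assert hits <= 2  # >= 18/20 seeds non-significant

    def test_training_split_only_for_clinical_outcomes(self, rng):
        n = 40
        cohort = make_cohort(n, rng)
        cohort["CombiWISE"] = rng.standard_normal(n)
        cohort["split"] = ["train"] * 30 + ["validation"] * 10
        panel = panel_from_matrix(
            pd.DataFrame({"b": rng.standard_normal(n)}, index=cohort.index)
        )
        rep = correlate(panel, cohort, ["CombiWISE", "age"], strata=["all"])
        assert rep.set_index("outcome").loc["CombiWISE", "n"] == 30
        assert rep.set_index("outcome").loc["age", "n"] == 40

    def test_constant_biomarker_cell_missing(self, rng):
        n = 20
        cohort = make_cohort(n, rng)
        cohort["CombiWISE"] = rng.standard_normal(n)
        panel = panel_from_matrix(
            pd.DataFrame({"b": np.ones(n)}, index=cohort.index)
        )
        rep = correlate(panel, cohort, ["CombiWISE"], strata=["all"])
        assert len(rep) == 0


class TestAgeBand:
    def test_noiseless_line_collapses_band(self):
        age = np.linspace(20, 70, 30)
        y = 0.01 * age - 2.0
        band = AgeReferenceBand().fit(age, y)
        assert band.resid_sd_ == pytest.approx(0.0, abs=1e-12)
        lo, hi = band.interval([45.0])
        assert hi[0] - lo[0] == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovered_within_two_standard_errors(self):
        rng = np.random.default_rng(8)
        n, b = 500, 0.008
        age = rng.uniform(20, 70, n)
        y = -1.5 + b * age + rng.normal(0, 0.12, n)
        band = AgeReferenceBand().fit(age, y)
        se = band.resid_sd_ / np.sqrt(band.sxx_)
        assert abs(band.slope_ - b) < 2 * se

    def test_prediction_interval_coverage(self):
        # textbook PI: fresh draws from the same model covered ~95%
        rng = np.random.default_rng(21)
        n, sigma = 500, 0.12
        age = rng.uniform(20, 70, n)
        y = -1.5 + 0.008 * age + rng.normal(0, sigma, n)
        band = AgeReferenceBand().fit(age, y)
        fresh_age = rng.uniform(20, 70, 2000)
        fresh_y = -1.5 + 0.008 * fresh_age + rng.normal(0, sigma, 2000)
        lo, hi = band.interval(fresh_age)
        coverage = np.mean((fresh_y >= lo) & (fresh_y <= hi))
        assert 0.93 <= coverage <= 0.97

    def test_band_width_minimal_at_mean_age(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(20, 70, 100)
        y = 0.01 * age + rng.normal(0, 0.1, 100)
        band = AgeReferenceBand().fit(age, y)
        grid = np.linspace(20, 70, 200)
        lo, hi = band.interval(grid)
        widths = hi - lo
        assert abs(grid[np.argmin(widths)] - band.age_mean_) < 1.0

    def test_degenerate_age_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            AgeReferenceBand().fit(np.full(10, 50.0), np.arange(10.0))


class TestCallAbnormal:
    def build(self, rng, n=500, shift=0.0, diagnosis="HV"):
        age = rng.uniform(20, 70, n)
        y = -1.5 + 0.008 * age + rng.normal(0, 0.12, n) + shift
        cohort = pd.DataFrame(
            {"age": age, "diagnosis": diagnosis},
            index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id"),
        )
        panel = panel_from_matrix(pd.DataFrame({"b": y}, index=cohort.index))
        return cohort, panel

    def test_reference_cohort_abnormal_rate_is_upper_tail(self):
        rng = np.random.default_rng(31)
        cohort, panel = self.build(rng)
        band = AgeReferenceBand().fit(cohort["age"], panel.values["b"].to_numpy())
        calls, fractions = call_abnormal(band, panel, cohort, "b")
        assert 0.0 <= fractions["HV"] <= 0.06

    def test_shifted_group_abnormal_at_normal_tail_rate(self):
        # a group shifted +3 residual sd exceeds the upper bound of the
        # two-sided 95% band at roughly the normal tail rate 1 - Phi(t - 3)
        rng = np.random.default_rng(32)
        cohort, panel = self.build(rng, n=2000)
        band = AgeReferenceBand().fit(cohort["age"], panel.values["b"].to_numpy())
        sick_cohort, sick_panel = self.build(rng, n=2000, shift=3 * 0.12, diagnosis="MS-PP")
        calls, fractions = call_abnormal(band, sick_panel, sick_cohort, "b")
        expected = 1.0 - stats.norm.cdf(band.t_crit_ - 3.0)
        assert fractions["MS-PP"] == pytest.approx(expected, abs=0.05)
        assert fractions["MS-PP"] > 0.8

    def test_extrapolated_ages_flagged(self):
        rng = np.random.default_rng(33)
        cohort, panel = self.build(rng, n=50)
        band = AgeReferenceBand().fit(cohort["age"], panel.values["b"].to_numpy())
        far = pd.DataFrame(
            {"age": [95.0], "diagnosis": ["HV"]},
            index=pd.Index(["X1"], name="subject_id"),
        )
        far_panel = panel_from_matrix(pd.DataFrame({"b": [0.0]}, index=far.index))
        calls, _ = call_abnormal(band, far_panel, far, "b")
        assert bool(calls["extrapolated"].iloc[0])

    def test_empty_group_fraction_missing(self):
        rng = np.random.default_rng(34)
        cohort, panel = self.build(rng, n=50)
        band = AgeReferenceBand().fit(cohort["age"], panel.values["b"].to_numpy())
        calls, fractions = call_abnormal(band, panel, cohort, "b")
        assert "NIND" not in fractions.index


class TestCompareGroups:
    def test_identical_samples_give_p_one(self):
        res = pd.Series(
            np.tile(np.arange(10.0), 2),
            index=pd.Index([f"S{i}" for i in range(20)], name="subject_id"),
        )
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=res.index)
        rep = compare_groups(res, groups)
        assert rep["p_value"].iloc[0] > 0.9

    def test_type_i_error_rate_controlled(self):
        rejections = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(4000 + seed)
            res = pd.Series(
                rng.standard_normal(200),
                index=pd.Index([f"S{i}" for i in range(200)], name="subject_id"),
            )
            groups = pd.Series(["a"] * 100 + ["b"] * 100, index=res.index)
            rep = compare_groups(res, groups)
            if rep["p_value"].iloc[0] <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_shifted_groups_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(5000 + seed)
            x = rng.standard_normal(30)
            y = rng.standard_normal(30) + 2.0  # 2 sd shift
            res = pd.Series(
                np.concatenate([x, y]),
                index=pd.Index([f"S{i}" for i in range(60)], name="subject_id"),
            )
            groups = pd.Series(["a"] * 30 + ["b"] * 30, index=res.index)
            if compare_groups(res, groups)["q_value"].iloc[0] <= 0.05:
                hits += 1
        assert hits >= 19

    def test_all_pairs_tested_and_small_groups_skipped(self, rng):
        res = pd.Series(
            rng.standard_normal(31),
            index=pd.Index([f"S{i}" for i in range(31)], name="subject_id"),
        )
        groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10 + ["d"], index=res.index)
        rep = compare_groups(res, groups)
        assert len(rep) == 3  # (a,b), (a,c), (b,c); singleton d skipped

    def test_fewer_than_two_groups_rejected(self, rng):
        res = pd.Series(
            rng.standard_normal(5),
            index=pd.Index([f"S{i}" for i in range(5)], name="subject_id"),
        )
        with pytest.raises(ValueError):
            compare_groups(res, pd.Series(["a"] * 5, index=res.index))
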