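"""Associations of biomarkers with demographics, clinical outcomes and age.

Three analyses mirror how digital sway biomarkers are interpreted clinically:

* Pearson correlations (with Benjamini-Hochberg FDR within each report
  family) between subject-level biomarker values and demographic or
  clinical/imaging outcomes, stratified by diagnosis group.
* A healthy-volunteer age regression with its 95 % prediction interval:
  sway amplitude rises with age even in health, so an individual's value is
  judged against the band expected for their age rather than a fixed norm.
* A one-sided abnormality call — a value above the upper prediction bound
  at the subject's age exceeds what natural aging explains — summarized as
  the abnormal fraction per diagnosis group, plus pairwise Wilcoxon
  rank-sum comparisons of age residuals between groups.

The subject-level biomarker value entering these analyses is the mean of
the subject's non-outlier trial values.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from swaymetrics.panel import BiomarkerPanel

DEMOGRAPHICS = ("age", "sex", "height", "weight")


def subject_values(panel: BiomarkerPanel) -> pd.DataFrame:
    """Per-subject biomarker values: mean over non-outlier, non-missing trials."""
    masked = panel.masked_values
    return masked.groupby(level="subject_id").mean()


def _bh(p: np.ndarray, alpha: float) -> np.ndarray:
    q = np.full(len(p), np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        q[valid] = multipletests(p[valid], alpha=alpha, method="fdr_bh")[1]
    return q


def correlate(
    panel: BiomarkerPanel,
    cohort: pd.DataFrame,
    targets,
    strata=None,
    group_min: int = 10,
    min_pairs: int = 3,
    alpha: float = 0.05,
    training_only_outcomes: bool = True,
) -> pd.DataFrame:
    """Pearson correlations of biomarkers with outcomes, one BH family.

    ``cohort`` is indexed by subject_id.  When ``strata`` is None, each
    diagnosis group with at least ``group_min`` subjects forms a stratum,
    plus an "all" stratum.  Sex is encoded 0/1 (point-biserial).  Outcomes
    other than the basic demographics are restricted to training-split rows
    when a ``split`` column is present, so validation subjects never inform
    feature selection.  Cells with fewer than ``min_pairs`` complete pairs,
    or with a constant biomarker or outcome, are skipped.
    """
    subj = subject_values(panel)
    cohort = cohort.copy()
    if "sex" in cohort.columns and cohort["sex"].dtype == object:
        cohort["sex"] = (cohort["sex"] == "F").astype(float)
    if strata is None:
        counts = cohort["diagnosis"].value_counts()
        strata = ["all"] + sorted(counts.index[counts >= group_min])

    rows = []
    for stratum in strata:
        sub = cohort if stratum == "all" else cohort[cohort["diagnosis"] == stratum]
        for outcome in targets:
            if outcome not in sub.columns:
                continue
            use = sub
            if (
                training_only_outcomes
                and outcome not in DEMOGRAPHICS
                and "split" in sub.columns
            ):
                use = sub[sub["split"] == "train"]
            common = subj.index.intersection(use.index)
            y = use.loc[common, outcome].astype(float)
            for biomarker in subj.columns:
                x = subj.loc[common, biomarker]
                mask = x.notna() & y.notna()
                n = int(mask.sum())
                if n < min_pairs:
                    continue
                xv, yv = x[mask].to_numpy(), y[mask].to_numpy()
                if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                    continue
                r, p = stats.pearsonr(xv, yv)
                rows.append(
                    {
                        "biomarker": biomarker,
                        "outcome": outcome,
                        "stratum": stratum,
                        "r": r,
                        "p_value": p,
                        "n": n,
                    }
                )
    report = pd.DataFrame(rows)
    if len(report):
        report["q_value"] = _bh(report["p_value"].to_numpy(), alpha)
    return report


class AgeReferenceBand(BaseEstimator):
    """OLS age regression on a reference cohort with a 95 % prediction band.

    Fit biomarker ~ age on healthy volunteers; the prediction interval at
    age x is fit(x) +/- t_{1-level/2, n-2} * s * sqrt(1 + 1/n + (x-xbar)^2/Sxx),
    the textbook interval for a single new observation.  The band is
    narrowest at the mean reference age and widens towards the range edges.
    """

    def __init__(self, level: float = 0.95, extrapolation_years: float = 10.0):
        self.level = level
        self.extrapolation_years = extrapolation_years

    def fit(self, age, y):
        age = np.asarray(age, dtype=float)
        y = np.asarray(y, dtype=float)
        mask = ~(np.isnan(age) | np.isnan(y))
        age, y = age[mask], y[mask]
        n = len(age)
        if n < 5:
            raise ValueError(f"need at least 5 reference subjects, got {n}")
        sxx = float(np.sum((age - age.mean()) ** 2))
        if sxx <= 0:
            raise ValueError("degenerate age variance in reference cohort")
        slope, intercept, r, p, se = stats.linregress(age, y)
        resid = y - (intercept + slope * age)
        s2 = float(np.sum(resid**2) / (n - 2))
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.resid_sd_ = float(np.sqrt(s2))
        self.r_value_ = float(r)
        self.n_ = n
        self.age_mean_ = float(age.mean())
        self.sxx_ = sxx
        self.age_range_ = (float(age.min()), float(age.max()))
        self.t_crit_ = float(stats.t.ppf(0.5 + self.level / 2.0, n - 2))
        return self

    def predict(self, age) -> np.ndarray:
        check_is_fitted(self, "slope_")
        age = np.asarray(age, dtype=float)
        return self.intercept_ + self.slope_ * age

    def interval(self, age) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) prediction bounds for a new observation at each age."""
        check_is_fitted(self, "slope_")
        age = np.asarray(age, dtype=float)
        fit = self.predict(age)
        half = self.t_crit_ * self.resid_sd_ * np.sqrt(
            1.0 + 1.0 / self.n_ + (age - self.age_mean_) ** 2 / self.sxx_
        )
        return fit - half, fit + half

    def is_extrapolated(self, age) -> np.ndarray:
        """True where an age falls outside the reference range +/- window."""
        check_is_fitted(self, "age_range_")
        age = np.asarray(age, dtype=float)
        lo, hi = self.age_range_
        w = self.extrapolation_years
        return (age < lo - w) | (age > hi + w)


def fit_age_band(
    panel: BiomarkerPanel,
    cohort: pd.DataFrame,
    biomarker: str,
    reference_group: str = "HV",
    level: float = 0.95,
) -> AgeReferenceBand:
    """Fit the reference-age band for one biomarker on the HV cohort."""
    subj = subject_values(panel)
    ref = cohort[cohort["diagnosis"] == reference_group]
    common = subj.index.intersection(ref.index)
    band = AgeReferenceBand(level=level)
    band.fit(ref.loc[common, "age"], subj.loc[common, biomarker])
    return band


def call_abnormal(
    band: AgeReferenceBand,
    panel: BiomarkerPanel,
    cohort: pd.DataFrame,
    biomarker: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """One-sided abnormality calls and per-group abnormal fractions.

    A subject is abnormal when their value exceeds the upper prediction
    bound at their age — sway beyond what natural aging explains, in the
    direction of disability.  Groups with no callable subject get NaN.
    """
    subj = subject_values(panel)
    common = subj.index.intersection(cohort.index)
    values = subj.loc[common, biomarker]
    ages = cohort.loc[common, "age"].astype(float)
    _, upper = band.interval(ages)
    ok = values.notna() & ages.notna()
    abnormal = pd.Series(
        np.asarray(values > upper, dtype=float), index=values.index
    )
    abnormal[~ok] = np.nan
    calls = pd.DataFrame(
        {
            "value": values,
            "age": ages,
            "residual": values - band.predict(ages),
            "abnormal": abnormal,
            "extrapolated": band.is_extrapolated(ages),
            "diagnosis": cohort.loc[common, "diagnosis"],
        }
    )
    fractions = calls.groupby("diagnosis", observed=True)["abnormal"].mean()
    return calls, fractions


def compare_groups(
    residuals: pd.Series,
    groups: pd.Series,
    min_n: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of residuals between diagnosis groups.

    All unordered pairs of groups with at least ``min_n`` members are
    tested (two-sided Mann-Whitney U, the rank-sum test with tie
    correction); BH adjustment spans the pair family.  Groups smaller than
    ``min_n`` are skipped, mirroring how sparsely recruited diagnostic
    categories are handled.
    """
    residuals = residuals.dropna()
    groups = groups.loc[residuals.index]
    sizes = groups.value_counts()
    usable = sorted(sizes.index[sizes >= min_n])
    if len(usable) < 2:
        raise ValueError("need at least two groups with enough members")
    rows = []
    for g1, g2 in itertools.combinations(usable, 2):
        x = residuals[groups == g1].to_numpy()
        y = residuals[groups == g2].to_numpy()
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({"group_1": g1, "group_2": g2, "n_1": len(x), "n_2": len(y), "p_value": p})
    report = pd.DataFrame(rows)
    report["q_value"] = _bh(report["p_value"].to_numpy(), alpha)
    return report
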