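"""Test-retest reliability screening with ICC(2,1).

A biomarker is useful for longitudinal monitoring only if repeated trials of
the same subject agree.  The intraclass correlation coefficient ICC(2,1) —
two-way model, absolute agreement, single measurement, with trial number
playing the role of a rater — compares between-subject variance with
trial-to-trial variance within subjects:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

where MSR, MSC and MSE are the row (subject), column (trial) and residual
mean squares of the two-way ANOVA of the n x k ratings matrix.  The p-value
comes from F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.  Following
common interpretive guidelines, biomarkers with ICC at or below 0.5 are
considered to have poor reliability and are screened out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from swaymetrics.panel import BiomarkerPanel


def icc_2_1(ratings) -> tuple[float, float]:
    """ICC(2,1) and F-test p-value for an n-subject x k-trial matrix.

    Requires n >= 3 subjects, k >= 2 trials and no missing cells
    (complete-case selection is the caller's job).  Returns (nan, nan) when
    the ANOVA is degenerate (zero residual and zero subject variance).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    n, k = x.shape
    if n < 3:
        raise ValueError(f"ICC needs at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"ICC needs at least 2 trials, got {k}")
    if np.isnan(x).any():
        raise ValueError("ratings contain missing cells; drop incomplete subjects first")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (mse == 0 and msr == 0):
        return float("nan"), float("nan")
    icc = (msr - mse) / denom
    if mse == 0:
        p = 0.0
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


@dataclass
class ReliabilityReport:
    """Per-biomarker ICC screening table plus the pairing it was run on."""

    table: pd.DataFrame  # columns: icc, p_value, q_value, n_subjects, reliable
    trial_pair: str
    cutoff: float
    alpha: float

    @property
    def reliable(self) -> list[str]:
        return list(self.table.index[self.table["reliable"].fillna(False)])


class ReliabilityFilter(BaseEstimator):
    """Selects biomarkers whose test-retest ICC(2,1) exceeds a cutoff.

    Fit on a panel values frame indexed by (subject_id, trial_id) restricted
    to a trial pairing; per biomarker, subjects with both trials non-missing
    form the ratings matrix.  Biomarkers with fewer than ``min_subjects``
    complete subjects are skipped with a warning.  Benjamini-Hochberg
    adjusted q-values are reported across the screened biomarkers; the
    reliable set itself is defined by ``icc > cutoff`` as in standard
    reliability screening practice.
    """

    def __init__(self, cutoff: float = 0.5, alpha: float = 0.05, min_subjects: int = 3):
        self.cutoff = cutoff
        self.alpha = alpha
        self.min_subjects = min_subjects

    def fit(self, X: pd.DataFrame, y=None, pairing: tuple[str, str] | None = None):
        """Compute per-column ICCs from a (subject, trial)-indexed frame.

        ``pairing`` names the two trial ids to compare (default: the first
        two trial ids in sorted order).  Cells the caller has masked to NaN
        (missing or outlier-flagged) drop that subject for that biomarker
        only.
        """
        X = pd.DataFrame(X)
        if X.index.nlevels != 2:
            raise ValueError("expected a (subject_id, trial_id) MultiIndex")
        trials = sorted(X.index.get_level_values(1).unique())
        if pairing is None:
            if len(trials) < 2:
                raise ValueError("need at least two trials to assess reliability")
            pairing = (trials[0], trials[1])
        a = X.xs(pairing[0], level=1)
        b = X.xs(pairing[1], level=1)
        common = a.index.intersection(b.index)
        a, b = a.loc[common], b.loc[common]

        rows = {}
        skipped = []
        for col in X.columns:
            mask = a[col].notna() & b[col].notna()
            n = int(mask.sum())
            if n < self.min_subjects:
                skipped.append(col)
                rows[col] = (np.nan, np.nan, n)
                continue
            mat = np.column_stack([a.loc[mask, col], b.loc[mask, col]])
            icc, p = icc_2_1(mat)
            rows[col] = (icc, p, n)
        if skipped:
            warnings.warn(
                f"{len(skipped)} biomarker(s) skipped: fewer than "
                f"{self.min_subjects} complete subjects"
            )
        table = pd.DataFrame(rows, index=["icc", "p_value", "n_subjects"]).T
        if table["icc"].notna().sum() == 0:
            raise ValueError("no biomarker had enough complete subjects for ICC")
        q = np.full(len(table), np.nan)
        valid = table["p_value"].notna().to_numpy()
        if valid.any():
            q[valid] = multipletests(
                table.loc[valid, "p_value"], alpha=self.alpha, method="fdr_bh"
            )[1]
        table["q_value"] = q
        table["n_subjects"] = table["n_subjects"].astype(int)
        table["reliable"] = table["icc"] > self.cutoff
        table.loc[table["icc"].isna(), "reliable"] = False

        self.report_ = table
        self.icc_ = table["icc"]
        self.support_ = table["reliable"].to_numpy(dtype=bool)
        self.pairing_ = pairing
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict a panel frame to the reliable biomarkers."""
        check_is_fitted(self, "support_")
        keep = [c for c, s in zip(self.feature_names_in_, self.support_) if s]
        return pd.DataFrame(X)[keep]


def screen(
    panel: BiomarkerPanel,
    pairing: tuple[str, str] | None = None,
    cutoff: float = 0.5,
    alpha: float = 0.05,
) -> ReliabilityReport:
    """ICC(2,1) screen of a biomarker panel over a trial pairing.

    Outlier-flagged cells are treated as missing, so a single aberrant
    trial does not corrupt a biomarker's reliability estimate.
    """
    filt = ReliabilityFilter(cutoff=cutoff, alpha=alpha)
    filt.fit(panel.masked_values, pairing=pairing)
    return ReliabilityReport(
        table=filt.report_,
        trial_pair=f"{filt.pairing_[0]} vs {filt.pairing_[1]}",
        cutoff=cutoff,
        alpha=alpha,
    )
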