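"""Regularized linear models predicting disability scales from biomarkers.

Digital biomarker panels are strongly collinear (the same sway signal feeds
many measures), so three shrinkage strategies of increasing aggressiveness
are compared — Ridge (moderate shrinkage of all coefficients), Elastic Net,
and Lasso (sets redundant coefficients to zero) — each also in a
PCA-component variant where the model is fit on principal components rather
than raw biomarkers.  Hyperparameters are tuned by five-fold
cross-validation on the training split: ridge takes the CV-maximizing
penalty, while the l1-penalized families take the heaviest penalty within
one standard error of their best CV score (the glmnet ``lambda.1se``
convention, which stabilizes which features are selected).  The strategy
with the highest mean CV R^2 wins (ties break toward the sparser model,
then a fixed family order).  The winner is refit on the full training split and evaluated once
on the untouched validation split with Pearson's r, R^2, and Lin's
concordance correlation coefficient

    CCC = 2 r s_x s_y / (s_x^2 + s_y^2 + (xbar - ybar)^2),

which, unlike r, penalizes scale and location shifts between predictions
and observations; CCC <= |r| always.  Model performance is compared against
the best single biomarker (highest-|r| feature in training) fit by
univariate OLS, to check that aggregation adds value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.impute import SimpleImputer
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

#: tie-break order among families (preferred first on exact CV-R^2 ties)
FAMILY_ORDER = ("ridge", "elastic-net", "lasso")
DEFAULT_ALPHAS = tuple(np.logspace(-3, 3, 13))
DEFAULT_L1_RATIOS = (0.1, 0.3, 0.5, 0.7, 0.9)


def split_cohort(cohort: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0) -> pd.DataFrame:
    """Assign a subject-level train/validation split before any analysis.

    The split is by subject (all of a subject's trials inherit the label),
    deterministic under ``seed``, with round(n * train_fraction) training
    subjects.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    cohort = cohort.copy()
    subjects = np.asarray(cohort.index)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_train = int(round(len(subjects) * train_fraction))
    split = pd.Series("validation", index=cohort.index)
    split.iloc[order[:n_train]] = "train"
    cohort["split"] = split
    return cohort


def concordance_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient between two vectors.

    Uses population (1/n) variances, the standard estimator; equals 1 only
    for perfect agreement on the identity line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    vx, vy = x.var(), y.var()
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return float("nan")
    return float(2 * sxy / denom)


def _make_model(family: str, alpha: float, l1_ratio: float | None = None):
    if family == "ridge":
        return Ridge(alpha=alpha)
    if family == "lasso":
        return Lasso(alpha=alpha, max_iter=50000)
    if family == "elastic-net":
        return ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50000)
    raise ValueError(f"unknown model family: {family}")


def _family_grid(family: str):
    """(alpha, l1_ratio) combinations searched for one family."""
    if family in ("ridge", "lasso"):
        return [(a, None) for a in DEFAULT_ALPHAS]
    if family == "elastic-net":
        return [(a, l1) for a in DEFAULT_ALPHAS for l1 in DEFAULT_L1_RATIOS]
    raise ValueError(f"unknown model family: {family}")


class DisabilityScaleRegressor(RegressorMixin, BaseEstimator):
    """CV-selected regularized linear model of a disability scale.

    For each requested family (and, when ``use_pca`` is true, its
    PCA-component twin) a pipeline of median imputation, z-scoring on
    training folds, optional PCA, and the linear model is grid-searched
    with seeded five-fold CV scored by R^2.  The strategy with the best
    mean CV R^2 is refit on all training data.  Fitted attributes:

    - ``best_strategy_``: e.g. "ridge" or "lasso+pca"
    - ``best_params_``: winning hyperparameters
    - ``cv_r2_``: its mean CV R^2 (flagged weak if negative)
    - ``coef_``: Series of coefficients named by biomarker (raw-feature
      strategies) or by component
    - ``cv_results_``: per-strategy summary table
    """

    def __init__(
        self,
        families=FAMILY_ORDER,
        use_pca: bool = True,
        max_pca_components: int = 10,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.families = families
        self.use_pca = use_pca
        self.max_pca_components = max_pca_components
        self.cv = cv
        self.random_state = random_state

    def _strategy_names(self):
        for family in self.families:
            yield family
            if self.use_pca:
                yield f"{family}+pca"

    def _cv_search(self, X: np.ndarray, y: np.ndarray, folds, k_max: int) -> pd.DataFrame:
        """Mean CV R^2 for every (strategy, alpha, l1_ratio, n_components).

        Imputation, scaling and the (nested) PCA basis are computed once per
        fold and shared across the hyperparameter grid; a rank-``k_max`` PCA
        fit on a training fold yields every smaller component count by
        truncation, which is what makes the sweep affordable.
        """
        prepared = []
        for tr_idx, va_idx in folds:
            Xtr, Xva = X[tr_idx], X[va_idx]
            med = np.nanmedian(Xtr, axis=0)
            med = np.where(np.isnan(med), 0.0, med)
            Xtr = np.where(np.isnan(Xtr), med, Xtr)
            Xva = np.where(np.isnan(Xva), med, Xva)
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Ztr, Zva = (Xtr - mu) / sd, (Xva - mu) / sd
            pca = PCA(n_components=min(k_max, len(tr_idx), Ztr.shape[1]))
            Ptr = pca.fit_transform(Ztr) if self.use_pca else None
            Pva = pca.transform(Zva) if self.use_pca else None
            prepared.append((Ztr, Zva, Ptr, Pva, y[tr_idx], y[va_idx]))

        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter at extreme alphas
            for family in self.families:
                for alpha, l1 in _family_grid(family):
                    scores, nnz = [], 0
                    for Ztr, Zva, _, _, ytr, yva in prepared:
                        m = _make_model(family, alpha, l1).fit(Ztr, ytr)
                        scores.append(r2_score(yva, m.predict(Zva)))
                        nnz = max(nnz, int(np.sum(np.abs(m.coef_) > 1e-12)))
                    rows.append(
                        {
                            "strategy": family,
                            "alpha": alpha,
                            "l1_ratio": np.nan if l1 is None else l1,
                            "n_components": np.nan,
                            "cv_r2": float(np.mean(scores)),
                            "cv_se": float(np.std(scores, ddof=1) / np.sqrt(len(scores))),
                            "n_nonzero": nnz,
                        }
                    )
                    if not self.use_pca:
                        continue
                    for k in range(1, min(k_max, prepared[0][2].shape[1]) + 1):
                        scores, nnz = [], 0
                        for _, _, Ptr, Pva, ytr, yva in prepared:
                            kk = min(k, Ptr.shape[1])
                            m = _make_model(family, alpha, l1).fit(Ptr[:, :kk], ytr)
                            scores.append(r2_score(yva, m.predict(Pva[:, :kk])))
                            nnz = max(nnz, int(np.sum(np.abs(m.coef_) > 1e-12)))
                        rows.append(
                            {
                                "strategy": f"{family}+pca",
                                "alpha": alpha,
                                "l1_ratio": np.nan if l1 is None else l1,
                                "n_components": k,
                                "cv_r2": float(np.mean(scores)),
                                "cv_se": float(
                                    np.std(scores, ddof=1) / np.sqrt(len(scores))
                                ),
                                "n_nonzero": nnz,
                            }
                        )
        return pd.DataFrame(rows)

    @staticmethod
    def _select_within_strategy(rows: pd.DataFrame) -> pd.Series:
        """Pick one hyperparameter row for a strategy.

        Ridge uses the CV-maximizing row.  The l1-penalized families use the
        one-standard-error rule: among rows whose mean CV R^2 lies within one
        standard error of the best, prefer the heaviest penalty (largest
        alpha, then largest l1_ratio) — the standard remedy for the
        over-selection of noise features at the CV-minimizing penalty.
        """
        best = rows.loc[rows["cv_r2"].idxmax()]
        family = best["strategy"].replace("+pca", "")
        if family == "ridge":
            return best
        threshold = best["cv_r2"] - best["cv_se"]
        eligible = rows[rows["cv_r2"] >= threshold]
        l1 = eligible["l1_ratio"].astype(float).fillna(0.0)
        return eligible.loc[(eligible["alpha"] + 1e-9 * l1).idxmax()]

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        keep = ~np.isnan(y)
        X, y = X.loc[keep], y[keep]
        if X.shape[1] < 2:
            raise ValueError("need at least 2 features")
        if len(X) < self.cv:
            raise ValueError(f"fewer training subjects ({len(X)}) than folds ({self.cv})")
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        folds = list(kf.split(X))
        k_max = min(self.max_pca_components, X.shape[1], len(X) - 1)

        Xa = X.to_numpy(dtype=float)
        grid = self._cv_search(Xa, y, folds, k_max)

        # per-strategy best hyperparameters, then winner by mean CV R^2;
        # ties -> fewer nonzero coefficients -> fixed family order
        rank = {n: i for i, n in enumerate(self._strategy_names())}
        per_strategy = pd.DataFrame(
            [self._select_within_strategy(g) for _, g in grid.groupby("strategy")]
        ).set_index("strategy")
        best = min(
            per_strategy.index,
            key=lambda n: (
                -per_strategy.loc[n, "cv_r2"],
                per_strategy.loc[n, "n_nonzero"],
                rank[n],
            ),
        )
        row = per_strategy.loc[best]
        family = best.replace("+pca", "")
        params = {"alpha": float(row["alpha"])}
        if row["l1_ratio"] is not None and not pd.isna(row["l1_ratio"]):
            params["l1_ratio"] = float(row["l1_ratio"])
        if row["n_components"] is not None and not pd.isna(row["n_components"]):
            params["n_components"] = int(row["n_components"])

        steps = [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
        ]
        if "n_components" in params:
            steps.append(("pca", PCA(n_components=params["n_components"])))
        steps.append(
            ("model", _make_model(family, params["alpha"], params.get("l1_ratio")))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pipeline = Pipeline(steps).fit(X, y)

        self.best_strategy_ = best
        self.best_params_ = params
        self.cv_r2_ = float(row["cv_r2"])
        self.weak_ = self.cv_r2_ < 0
        self.model_ = pipeline
        self.cv_results_ = per_strategy
        self.cv_grid_ = grid
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        coefs = self.model_.named_steps["model"].coef_
        if "pca" in self.model_.named_steps:
            names = [f"PC{i + 1}" for i in range(len(coefs))]
        else:
            names = list(X.columns)
        self.coef_ = pd.Series(coefs, index=names)
        self.intercept_ = float(self.model_.named_steps["model"].intercept_)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(pd.DataFrame(X))


@dataclass
class ModelReport:
    """Winning model summary with blind-validation metrics."""

    outcome: str
    feature_set: str
    strategy: str
    params: dict
    cv_r2: float
    coefficients: dict
    validation: dict  # r, r2, ccc, n
    best_single: dict = field(default_factory=dict)  # name + same metrics
    weak: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def regression_metrics(y_true, y_pred) -> dict:
    """Pearson r, coefficient of determination and CCC of predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    r2 = 1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot if ss_tot > 0 else float("nan")
    if np.ptp(y_pred) == 0 or np.ptp(y_true) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(y_true, y_pred)[0])
    return {"r": r, "r2": float(r2), "ccc": concordance_ccc(y_pred, y_true), "n": len(y_true)}


def best_single_predictor(X: pd.DataFrame, y) -> str:
    """Feature with the highest-magnitude training correlation to the outcome."""
    y = np.asarray(y, dtype=float)
    best, best_r = None, -1.0
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
            continue
        r = abs(stats.pearsonr(x[mask], y[mask])[0])
        if r > best_r:
            best, best_r = col, r
    if best is None:
        raise ValueError("no usable feature for a single-predictor baseline")
    return best


def validate_model(
    model: DisabilityScaleRegressor,
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    outcome: str = "",
    feature_set: str = "",
) -> ModelReport:
    """Blind-validation report for a fitted model and its univariate baseline.

    The baseline is the best single training predictor fit by univariate
    OLS on the training split (median-imputed), evaluated on the same
    validation subjects with the same metrics.
    """
    y_val = np.asarray(y_val, dtype=float)
    keep = ~np.isnan(y_val)
    X_val, y_val = X_val.loc[keep], y_val[keep]
    metrics = regression_metrics(y_val, model.predict(X_val))

    y_train = np.asarray(y_train, dtype=float)
    keep_tr = ~np.isnan(y_train)
    Xt, yt = X_train.loc[keep_tr], y_train[keep_tr]
    name = best_single_predictor(Xt, yt)
    med = float(np.nanmedian(Xt[name]))
    x_tr = Xt[name].fillna(med).to_numpy()
    slope, intercept = np.polyfit(x_tr, yt, 1)
    x_va = X_val[name].fillna(med).to_numpy()
    single_metrics = regression_metrics(y_val, intercept + slope * x_va)
    single_metrics["name"] = name

    return ModelReport(
        outcome=outcome,
        feature_set=feature_set,
        strategy=model.best_strategy_,
        params={k: float(v) if np.isscalar(v) else v for k, v in model.best_params_.items()},
        cv_r2=model.cv_r2_,
        coefficients={k: float(v) for k, v in model.coef_.items()},
        validation=metrics,
        best_single=single_metrics,
        weak=model.weak_,
    )
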