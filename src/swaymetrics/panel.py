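"""Assembly of the named 60 + 16 digital-biomarker panels.

Postural sway: the 4 measures x 3 axes grid per stance (EO-FA, EO-FT,
EC-FT) gives 36 stance biomarkers; two condition ratios per (measure, axis)
— EC-FT:EO-FT (the Romberg ratio, effect of removing vision) and
EO-FT:EO-FA (effect of narrowing the stance) — add 24 more, for 60 total.

Pronator drift: Net-axis measures per hand are relabeled dominant ("Dom") /
non-dominant ("Ndom") from the subject's declared hand dominance, and
combined into "Sum" and "Diff" columns, for 4 measures x 4 roles = 16.

Ratios and sums are computed on the raw measurement scale and then every
biomarker is log10-transformed (so a ratio column equals the difference of
its constituent stance columns on the log scale).  The Dom/Ndom difference
is defined on the log scale — log10(Dom) - log10(Ndom), i.e. the log of the
raw ratio — because a raw difference can be non-positive and has no
log-transform.  Non-positive raw values (degenerate flat signals) become
missing cells; columns are never dropped, so the panel always has exactly
60 sway and 16 drift columns.

Biomarker naming grammar: ``<measure>_<axis>_<condition>``, e.g.
``RMS_Net_ECFT``, ``Jerk_ML_Romberg``, ``SC_Net_Diff``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from swaymetrics.features import DEFAULT_BAND, MEASURES, AXES, trace_features
from swaymetrics.ingest import RawTrace, SWAY_CONDITIONS, DRIFT_CONDITIONS, calibrate, trim

_COND_TOKEN = {"EO-FA": "EOFA", "EO-FT": "EOFT", "EC-FT": "ECFT"}
#: ratio definitions: name -> (numerator stance, denominator stance)
RATIOS = {"Romberg": ("EC-FT", "EO-FT"), "FTFA": ("EO-FT", "EO-FA")}
DRIFT_ROLES = ("Dom", "Ndom", "Sum", "Diff")

SWAY_COLUMNS = [
    f"{m}_{a}_{c}"
    for c in [_COND_TOKEN[s] for s in SWAY_CONDITIONS] + list(RATIOS)
    for m in MEASURES
    for a in AXES
]
DRIFT_COLUMNS = [f"{m}_Net_{role}" for role in DRIFT_ROLES for m in MEASURES]

FLAG_OK = "ok"
FLAG_MISSING = "missing"
FLAG_OUTLIER = "outlier"


@dataclass
class BiomarkerPanel:
    """Subject x trial biomarker matrix with per-cell quality flags.

    ``values`` holds log10-transformed biomarkers indexed by
    (subject_id, trial_id); ``flags`` is the same shape with entries in
    {"ok", "missing", "outlier"}.  Values are preserved when flagged;
    :attr:`masked_values` replaces non-ok cells with NaN for analyses.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    kind: str = "sway"

    def __post_init__(self):
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise ValueError("values and flags must be aligned")

    @property
    def masked_values(self) -> pd.DataFrame:
        return self.values.where(self.flags == FLAG_OK)

    @property
    def biomarkers(self) -> list[str]:
        return list(self.values.columns)

    def join(self, other: "BiomarkerPanel") -> "BiomarkerPanel":
        """Column-wise join of two panels (e.g. sway + drift -> combined)."""
        values = self.values.join(other.values, how="outer")
        flags = self.flags.join(other.flags, how="outer").fillna(FLAG_MISSING)
        return BiomarkerPanel(values=values, flags=flags, kind="combined")


def _panel_from_values(values: pd.DataFrame, kind: str) -> BiomarkerPanel:
    flags = pd.DataFrame(FLAG_OK, index=values.index, columns=values.columns)
    flags = flags.mask(values.isna(), FLAG_MISSING)
    return BiomarkerPanel(values=values, flags=flags, kind=kind)


def _check_duplicates(df: pd.DataFrame, keys: list[str]) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"duplicate feature entries: {df.loc[dup, keys].values[:5]}")


def _safe_log10(raw: pd.DataFrame) -> pd.DataFrame:
    """log10 with non-positive raw values mapped to missing (NaN)."""
    return np.log10(raw.where(raw > 0))


def build_sway_panel(features: pd.DataFrame) -> BiomarkerPanel:
    """Assemble the 60-column postural sway panel from tidy feature rows.

    ``features`` has columns subject_id, trial_id, condition, measure,
    axis, value (raw scale).  Every output column exists regardless of
    input completeness; unavailable cells are missing.  A ratio cell is
    missing whenever either constituent is missing or the denominator is
    non-positive on the raw scale.
    """
    _check_duplicates(features, ["subject_id", "trial_id", "condition", "measure", "axis"])
    wide = features.pivot_table(
        index=["subject_id", "trial_id"],
        columns=["condition", "measure", "axis"],
        values="value",
        aggfunc="first",
        dropna=False,
    )

    def raw_col(cond: str, m: str, a: str) -> pd.Series:
        key = (cond, m, a)
        if key in wide.columns:
            return wide[key]
        return pd.Series(np.nan, index=wide.index)

    out = {}
    for cond in SWAY_CONDITIONS:
        for m in MEASURES:
            for a in AXES:
                out[f"{m}_{a}_{_COND_TOKEN[cond]}"] = _safe_log10(
                    raw_col(cond, m, a).to_frame()
                ).iloc[:, 0]
    for rname, (num_cond, den_cond) in RATIOS.items():
        for m in MEASURES:
            for a in AXES:
                num = raw_col(num_cond, m, a)
                den = raw_col(den_cond, m, a)
                ratio = (num / den).where((num > 0) & (den > 0))
                out[f"{m}_{a}_{rname}"] = np.log10(ratio)
    values = pd.DataFrame(out, index=wide.index)[SWAY_COLUMNS]
    return _panel_from_values(values, "sway")


def build_drift_panel(features: pd.DataFrame, dominance) -> BiomarkerPanel:
    """Assemble the 16-column pronator drift panel.

    ``features`` has the tidy schema of :func:`build_sway_panel` with
    conditions "left"/"right" (only the Net axis is used: device
    orientation in the hand is uncontrolled, so directional M-L/A-P
    components are not interpretable).  ``dominance`` maps subject_id ->
    "left" or "right"; trials for subjects with no declared dominance are
    excluded with a warning.
    """
    _check_duplicates(features, ["subject_id", "trial_id", "condition", "measure", "axis"])
    dominance = dict(dominance)
    bad = {h for h in dominance.values() if h not in ("left", "right")}
    if bad:
        raise ValueError(f"unknown hand label(s) in dominance: {sorted(bad)}")
    feats = features[features["axis"] == "Net"]
    wide = feats.pivot_table(
        index=["subject_id", "trial_id"],
        columns=["condition", "measure"],
        values="value",
        aggfunc="first",
        dropna=False,
    )
    known = wide.index.get_level_values("subject_id").map(lambda s: s in dominance)
    if not known.all():
        dropped = sorted(set(wide.index.get_level_values("subject_id")[~known]))
        warnings.warn(f"subjects with no declared hand dominance excluded: {dropped}")
        wide = wide[known]

    def raw_col(cond: str, m: str) -> pd.Series:
        key = (cond, m)
        if key in wide.columns:
            return wide[key]
        return pd.Series(np.nan, index=wide.index)

    subjects = wide.index.get_level_values("subject_id")
    out = {}
    for m in MEASURES:
        left = raw_col("left", m)
        right = raw_col("right", m)
        dom_is_right = pd.Series(
            [dominance[s] == "right" for s in subjects], index=wide.index
        )
        dom = right.where(dom_is_right, left)
        ndom = left.where(dom_is_right, right)
        log_dom = np.log10(dom.where(dom > 0))
        log_ndom = np.log10(ndom.where(ndom > 0))
        out[f"{m}_Net_Dom"] = log_dom
        out[f"{m}_Net_Ndom"] = log_ndom
        total = (dom + ndom).where(dom.notna() & ndom.notna())
        out[f"{m}_Net_Sum"] = np.log10(total.where(total > 0))
        out[f"{m}_Net_Diff"] = log_dom - log_ndom
    values = pd.DataFrame(out, index=wide.index)[DRIFT_COLUMNS]
    return _panel_from_values(values, "drift")


class IQROutlierFlagger(TransformerMixin, BaseEstimator):
    """Tukey-fence outlier flagger fitted on reference (training) rows.

    Per column, Q1 and Q3 are computed with linear (type-7) interpolation on
    the rows seen in :meth:`fit`; cells outside
    [Q1 - m*IQR, Q3 + m*IQR] with ``m = fence_multiplier`` are flagged.
    ``transform`` masks flagged cells to NaN; the original values survive in
    the input.
    """

    def __init__(self, fence_multiplier: float = 1.5):
        self.fence_multiplier = fence_multiplier

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        all_missing = X.isna().all(axis=0)
        if all_missing.any():
            warnings.warn(
                f"columns with no reference values left unfenced: "
                f"{list(X.columns[all_missing])[:5]}..."
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            q1 = X.quantile(0.25, interpolation="linear")
            q3 = X.quantile(0.75, interpolation="linear")
        iqr = q3 - q1
        self.q1_, self.q3_ = q1, q3
        self.lower_ = q1 - self.fence_multiplier * iqr
        self.upper_ = q3 + self.fence_multiplier * iqr
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def flag(self, X: pd.DataFrame) -> pd.DataFrame:
        """Boolean frame: True where a cell lies outside its fitted fences."""
        check_is_fitted(self, "lower_")
        X = pd.DataFrame(X)
        return X.lt(self.lower_, axis=1) | X.gt(self.upper_, axis=1)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X).where(~self.flag(X))


def flag_outliers(
    panel: BiomarkerPanel,
    fence_multiplier: float = 1.5,
    reference_rows=None,
) -> BiomarkerPanel:
    """Return a panel with outlier flags set from training-row Tukey fences.

    ``reference_rows`` selects the rows (e.g. training subjects' trials)
    whose quantiles define the fences; by default all rows are used.
    Values are preserved — downstream consumers consult the flags.
    """
    ref = panel.values if reference_rows is None else panel.values.loc[reference_rows]
    flagger = IQROutlierFlagger(fence_multiplier=fence_multiplier).fit(ref)
    is_out = flagger.flag(panel.values) & (panel.flags == FLAG_OK)
    flags = panel.flags.mask(is_out, FLAG_OUTLIER)
    return BiomarkerPanel(values=panel.values.copy(), flags=flags, kind=panel.kind)


def write_panel(panel: BiomarkerPanel, values_path, flags_path=None) -> None:
    """Write a panel as wide CSV (one row per subject-trial) + sidecar flags."""
    panel.values.to_csv(values_path)
    if flags_path is not None:
        panel.flags.to_csv(flags_path)


def read_panel(values_path, flags_path=None, kind: str = "sway") -> BiomarkerPanel:
    """Read a panel written by :func:`write_panel`.

    Without a flags sidecar, NaN cells are flagged missing and everything
    else ok.
    """
    values = pd.read_csv(values_path, index_col=[0, 1])
    values.index.names = ["subject_id", "trial_id"]
    if flags_path is None:
        return _panel_from_values(values, kind)
    flags = pd.read_csv(flags_path, index_col=[0, 1])
    flags.index.names = ["subject_id", "trial_id"]
    return BiomarkerPanel(values=values, flags=flags, kind=kind)


def extract_panels(
    traces: list[RawTrace],
    dominance=None,
    band: tuple[float, float] = DEFAULT_BAND,
    target_duration: float = 9.0,
) -> tuple[BiomarkerPanel, BiomarkerPanel | None]:
    """Trim, calibrate and featurize traces into (sway, drift) panels.

    Traces that fail trimming or calibration are skipped with a warning and
    their cells stay missing.  ``dominance`` is required to build the drift
    panel; with no drift traces or no dominance the second element is None.
    """
    rows = []
    for tr in traces:
        try:
            cal = calibrate(trim(tr, target_duration))
        except ValueError as exc:
            warnings.warn(f"trace skipped: {exc}")
            continue
        for (measure, axis), value in trace_features(cal, band).items():
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "trial_id": tr.trial_id,
                    "test": tr.test,
                    "condition": tr.condition,
                    "measure": measure,
                    "axis": axis,
                    "value": value,
                }
            )
    feats = pd.DataFrame(rows)
    sway_feats = feats[feats["condition"].isin(SWAY_CONDITIONS)] if len(feats) else feats
    drift_feats = feats[feats["condition"].isin(DRIFT_CONDITIONS)] if len(feats) else feats
    if len(sway_feats) == 0:
        raise ValueError("no usable sway traces")
    sway_panel = build_sway_panel(sway_feats)
    drift_panel = None
    if len(drift_feats) and dominance is not None:
        drift_panel = build_drift_panel(drift_feats, dominance)
    return sway_panel, drift_panel
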