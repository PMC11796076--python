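"""Biomarker panel assembly, ratios, hand relabeling and outlier fences."""

import numpy as np
import pandas as pd
import pytest

from swaymetrics.features import AXES, MEASURES
from swaymetrics.panel import (
    DRIFT_COLUMNS,
    FLAG_MISSING,
    FLAG_OUTLIER,
    IQROutlierFlagger,
    SWAY_COLUMNS,
    build_drift_panel,
    build_sway_panel,
    flag_outliers,
    read_panel,
    write_panel,
)

STANCES = ("EO-FA", "EO-FT", "EC-FT")


def tidy_sway(value_fn, subjects=("A",), trials=("T1",), conditions=STANCES):
    rows = []
    for s in subjects:
        for t in trials:
            for c in conditions:
                for m in MEASURES:
                    for a in AXES:
                        rows.append(
                            {
                                "subject_id": s,
                                "trial_id": t,
                                "condition": c,
                                "measure": m,
                                "axis": a,
                                "value": value_fn(s, t, c, m, a),
                            }
                        )
    return pd.DataFrame(rows)


class TestSwayPanel:
    def test_full_features_yield_exactly_60_columns(self):
        panel = build_sway_panel(tidy_sway(lambda *k: 1.0 + hash(k) % 7))
        assert list(panel.values.columns) == SWAY_COLUMNS
        assert len(panel.biomarkers) == 60
        assert panel.values.notna().all().all()

    def test_identical_conditions_make_romberg_ratios_zero(self):
        panel = build_sway_panel(tidy_sway(lambda s, t, c, m, a: 2.5))
        romberg = [c for c in SWAY_COLUMNS if c.endswith("_Romberg")]
        assert len(romberg) == 12
        assert np.allclose(panel.values[romberg], 0.0)

    def test_log_ratio_identity(self):
        rng = np.random.default_rng(5)
        vals = {}

        def value(s, t, c, m, a):
            return vals.setdefault((s, t, c, m, a), float(rng.uniform(0.5, 4)))

        panel = build_sway_panel(tidy_sway(value))
        for m in MEASURES:
            for a in AXES:
                lhs = panel.values[f"{m}_{a}_ECFT"] - panel.values[f"{m}_{a}_EOFT"]
                np.testing.assert_allclose(lhs, panel.values[f"{m}_{a}_Romberg"], atol=1e-12)
                lhs2 = panel.values[f"{m}_{a}_EOFT"] - panel.values[f"{m}_{a}_EOFA"]
                np.testing.assert_allclose(lhs2, panel.values[f"{m}_{a}_FTFA"], atol=1e-12)

    def test_missing_condition_propagates_but_keeps_columns(self):
        panel = build_sway_panel(
            tidy_sway(lambda s, t, c, m, a: 2.0, conditions=("EO-FT", "EC-FT"))
        )
        assert len(panel.biomarkers) == 60  # columns conserved
        eofa = [c for c in SWAY_COLUMNS if c.endswith("_EOFA")]
        ftfa = [c for c in SWAY_COLUMNS if c.endswith("_FTFA")]
        romberg = [c for c in SWAY_COLUMNS if c.endswith("_Romberg")]
        assert panel.values[eofa].isna().all().all()
        assert panel.values[ftfa].isna().all().all()
        assert panel.values[romberg].notna().all().all()
        assert (panel.flags[eofa] == FLAG_MISSING).all().all()

    def test_nonpositive_raw_value_becomes_missing(self):
        panel = build_sway_panel(
            tidy_sway(lambda s, t, c, m, a: 0.0 if (m, a, c) == ("RMS", "ML", "EO-FA") else 1.0)
        )
        assert np.isnan(panel.values.loc[("A", "T1"), "RMS_ML_EOFA"])
        assert np.isnan(panel.values.loc[("A", "T1"), "RMS_ML_FTFA"])  # ratio denominator
        assert not np.isnan(panel.values.loc[("A", "T1"), "RMS_ML_Romberg"])

    def test_duplicate_entries_rejected(self):
        df = tidy_sway(lambda *k: 1.0)
        with pytest.raises(ValueError, match="duplicate"):
            build_sway_panel(pd.concat([df, df.iloc[[0]]], ignore_index=True))


def tidy_drift(value_fn, subjects=("A",), trials=("T1",)):
    rows = []
    for s in subjects:
        for t in trials:
            for hand in ("left", "right"):
                for m in MEASURES:
                    rows.append(
                        {
                            "subject_id": s,
                            "trial_id": t,
                            "condition": hand,
                            "measure": m,
                            "axis": "Net",
                            "value": value_fn(s, t, hand, m),
                        }
                    )
    return pd.DataFrame(rows)


class TestDriftPanel:
    def test_full_features_yield_exactly_16_columns(self):
        panel = build_drift_panel(tidy_drift(lambda *k: 2.0), {"A": "right"})
        assert list(panel.values.columns) == DRIFT_COLUMNS
        assert len(panel.biomarkers) == 16

    def test_identical_hands_make_diff_zero(self):
        panel = build_drift_panel(tidy_drift(lambda *k: 3.0), {"A": "left"})
        diff = [c for c in DRIFT_COLUMNS if c.endswith("_Diff")]
        assert np.allclose(panel.values[diff], 0.0)

    def test_sum_and_diff_closed_forms(self):
        panel = build_drift_panel(
            tidy_drift(lambda s, t, hand, m: 10.0 if hand == "right" else 1.0),
            {"A": "right"},
        )
        row = panel.values.loc[("A", "T1")]
        assert row["RMS_Net_Sum"] == pytest.approx(np.log10(11.0))
        assert row["RMS_Net_Diff"] == pytest.approx(1.0)
        assert row["RMS_Net_Dom"] == pytest.approx(1.0)
        assert row["RMS_Net_Ndom"] == pytest.approx(0.0)

    def test_swapping_dominance_swaps_columns_and_negates_diff(self):
        tidy = tidy_drift(lambda s, t, hand, m: 5.0 if hand == "right" else 2.0)
        right = build_drift_panel(tidy, {"A": "right"}).values.loc[("A", "T1")]
        left = build_drift_panel(tidy, {"A": "left"}).values.loc[("A", "T1")]
        for m in MEASURES:
            assert right[f"{m}_Net_Dom"] == pytest.approx(left[f"{m}_Net_Ndom"])
            assert right[f"{m}_Net_Diff"] == pytest.approx(-left[f"{m}_Net_Diff"])
            assert right[f"{m}_Net_Sum"] == pytest.approx(left[f"{m}_Net_Sum"])

    def test_missing_dominance_excludes_subject_with_warning(self):
        tidy = tidy_drift(lambda *k: 1.0, subjects=("A", "B"))
        with pytest.warns(UserWarning, match="dominance"):
            panel = build_drift_panel(tidy, {"A": "right"})
        assert list(panel.values.index.get_level_values("subject_id")) == ["A"]

    def test_unknown_hand_label_rejected(self):
        with pytest.raises(ValueError, match="unknown hand"):
            build_drift_panel(tidy_drift(lambda *k: 1.0), {"A": "ambidextrous"})


class TestOutlierFlagging:
    def test_tukey_fence_example(self):
        # [1,2,3,4,100]: type-7 quantiles give Q1=2, Q3=4, upper fence 7
        X = pd.DataFrame({"b": [1.0, 2.0, 3.0, 4.0, 100.0]})
        flagger = IQROutlierFlagger().fit(X)
        assert flagger.q1_["b"] == pytest.approx(2.0)
        assert flagger.q3_["b"] == pytest.approx(4.0)
        assert flagger.upper_["b"] == pytest.approx(7.0)
        assert list(flagger.flag(X)["b"]) == [False, False, False, False, True]

    def test_brute_force_fences_on_random_columns(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 6)), columns=list("abcdef"))
        flagger = IQROutlierFlagger().fit(X)
        flags = flagger.flag(X)
        for col in X.columns:
            q1, q3 = np.quantile(X[col], [0.25, 0.75])
            lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
            expected = (X[col] < lo) | (X[col] > hi)
            assert (flags[col] == expected).all()

    def test_constant_column_flags_nothing(self):
        X = pd.DataFrame({"b": np.full(10, 3.3)})
        assert not IQROutlierFlagger().fit(X).flag(X).any().any()

    def test_infinite_fence_flags_nothing(self, rng):
        X = pd.DataFrame({"b": rng.standard_normal(50)})
        assert not IQROutlierFlagger(fence_multiplier=np.inf).fit(X).flag(X).any().any()

    def test_flag_outliers_sets_flags_and_keeps_values(self):
        idx = pd.MultiIndex.from_product(
            [["A", "B", "C", "D", "E"], ["T1"]], names=["subject_id", "trial_id"]
        )
        values = pd.DataFrame({"b": [1.0, 2.0, 3.0, 4.0, 100.0]}, index=idx)
        flags = pd.DataFrame("ok", index=idx, columns=["b"])
        from swaymetrics.panel import BiomarkerPanel

        panel = flag_outliers(BiomarkerPanel(values=values, flags=flags))
        assert panel.flags.loc[("E", "T1"), "b"] == FLAG_OUTLIER
        assert panel.values.loc[("E", "T1"), "b"] == 100.0  # value preserved
        assert np.isnan(panel.masked_values.loc[("E", "T1"), "b"])


class TestPanelRoundTrip:
    def test_csv_round_trip_preserves_values_and_flags(self, tmp_path, small_study):
        from swaymetrics.panel import extract_panels

        sway_panel, _ = extract_panels(
            small_study["traces"], dominance=small_study["cohort"]["dominance"].to_dict()
        )
        write_panel(sway_panel, tmp_path / "v.csv", tmp_path / "f.csv")
        back = read_panel(tmp_path / "v.csv", tmp_path / "f.csv")
        pd.testing.assert_frame_equal(back.values, sway_panel.values)
        pd.testing.assert_frame_equal(back.flags, sway_panel.flags)
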