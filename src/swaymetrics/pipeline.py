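"""End-to-end orchestration: simulate -> extract -> reliability -> associate -> model.

Every stage is a pure function of (inputs, config, seeds); the pipeline
writes its artifacts under one output directory and returns a manifest
listing each file with a content hash, so two runs with the same config are
verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from swaymetrics import simulate as sim
from swaymetrics.association import (
    call_abnormal,
    compare_groups,
    correlate,
    fit_age_band,
    subject_values,
)
from swaymetrics.features import DEFAULT_BAND
from swaymetrics.ingest import read_traces, write_traces_csv
from swaymetrics.modeling import (
    DisabilityScaleRegressor,
    split_cohort,
    validate_model,
)
from swaymetrics.panel import extract_panels, flag_outliers, write_panel
from swaymetrics.reliability import screen

logger = logging.getLogger(__name__)

#: default (feature set, outcome) model plan: test-specific models target
#: the matching examination subpanel — drift biomarkers model the dominant
#: hand cerebellar score, the subpanel they actually track — and combined
#: models target the global disability scales.
DEFAULT_MODEL_PLAN = (
    ("sway", "NeurEx Postural Sway"),
    ("drift", "NeurEx Cerebellar Dom"),
    ("combined", "EDSS"),
    ("combined", "CombiWISE"),
    ("combined", "NeurEx"),
)


@dataclass
class PipelineConfig:
    """Every analysis knob of the pipeline, echoed into output metadata."""

    out_dir: str = "swaymetrics_out"
    traces_csv: str | None = None  # None -> simulate
    cohort_csv: str | None = None
    seed: int = 0
    n_subjects: int = 20
    trials_per_subject: int = 2
    band: tuple = DEFAULT_BAND
    target_duration: float = 9.0
    icc_cutoff: float = 0.5
    fence_multiplier: float = 1.5
    bh_alpha: float = 0.05
    train_fraction: float = 0.8
    age_band_biomarker: str = "RMS_Net_ECFT"
    run_models: bool = True
    model_plan: tuple = DEFAULT_MODEL_PLAN
    sim_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.traces_csv is not None and self.cohort_csv is None and self.run_models:
            raise ValueError(
                "config error: 'cohort_csv' is required when 'traces_csv' is "
                "given and modeling is enabled"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in d.items() if k in names})
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        if isinstance(cfg.model_plan, list):
            cfg.model_plan = tuple(tuple(p) for p in cfg.model_plan)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the artifact manifest.

    Stages fail loudly with the failing stage named; artifacts written
    before the failure are retained for inspection.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "files": {}, "log": {}}

    def record(path: Path):
        manifest["files"][path.name] = _sha256(path)

    stage = "simulate"
    try:
        if config.traces_csv is None:
            sway_params = sim.params_from_dict(
                {
                    "subject_count": config.n_subjects,
                    "trials_per_subject": config.trials_per_subject,
                    "rng_seed": config.seed,
                    **config.sim_overrides,
                }
            )
            cohort_params = sim.CohortSimParams(rng_seed=config.seed + 1)
            traces, cohort, truth = sim.simulate_cohort(sway_params, cohort_params)
            write_traces_csv(traces, out / "traces.csv")
            sim.write_cohort_csv(cohort, out / "cohort.csv")
            sim.write_ground_truth_json(truth, out / "ground_truth.json")
            record(out / "traces.csv")
            record(out / "cohort.csv")
            record(out / "ground_truth.json")
        else:
            traces = read_traces(config.traces_csv)
            cohort = (
                pd.read_csv(config.cohort_csv, index_col="subject_id")
                if config.cohort_csv
                else None
            )

        stage = "split"
        if cohort is not None and "split" not in cohort.columns:
            cohort = split_cohort(cohort, config.train_fraction, seed=config.seed)
            sim.write_cohort_csv(cohort, out / "cohort.csv")
            record(out / "cohort.csv")

        stage = "extract"
        dominance = cohort["dominance"].to_dict() if cohort is not None else None
        sway_panel, drift_panel = extract_panels(
            traces,
            dominance=dominance,
            band=tuple(config.band),
            target_duration=config.target_duration,
        )
        n_drift = len(drift_panel.biomarkers) if drift_panel is not None else 0
        logger.info(
            "extracted %d sway / %d drift biomarkers",
            len(sway_panel.biomarkers),
            n_drift,
        )
        manifest["log"]["biomarkers"] = (
            f"{len(sway_panel.biomarkers)} sway / {n_drift} drift biomarkers"
        )

        stage = "outliers"
        train_subjects = (
            set(cohort.index[cohort["split"] == "train"]) if cohort is not None else None
        )

        def train_rows(panel):
            if train_subjects is None:
                return None
            idx = panel.values.index
            return idx[idx.get_level_values("subject_id").isin(train_subjects)]

        sway_panel = flag_outliers(
            sway_panel, config.fence_multiplier, reference_rows=train_rows(sway_panel)
        )
        if drift_panel is not None:
            drift_panel = flag_outliers(
                drift_panel, config.fence_multiplier, reference_rows=train_rows(drift_panel)
            )
        write_panel(sway_panel, out / "sway_panel.csv", out / "sway_panel_flags.csv")
        record(out / "sway_panel.csv")
        record(out / "sway_panel_flags.csv")
        if drift_panel is not None:
            write_panel(drift_panel, out / "drift_panel.csv", out / "drift_panel_flags.csv")
            record(out / "drift_panel.csv")
            record(out / "drift_panel_flags.csv")

        stage = "reliability"
        reports = {}
        for name, panel in [("sway", sway_panel), ("drift", drift_panel)]:
            if panel is None:
                continue
            rep = screen(panel, cutoff=config.icc_cutoff, alpha=config.bh_alpha)
            rep.table.to_csv(out / f"reliability_{name}.csv", index_label="biomarker")
            record(out / f"reliability_{name}.csv")
            reports[name] = rep
            manifest["log"][f"reliable_{name}"] = len(rep.reliable)
            logger.info("%s: %d reliable biomarkers", name, len(rep.reliable))

        stage = "correlate"
        if cohort is not None:
            outcome_cols = [c for c in cohort.columns if c.startswith("NeurEx") or c in
                            ("EDSS", "CombiWISE")]
            targets = ["age", "sex", "height", "weight"] + outcome_cols
            reliable = reports["sway"].reliable
            if "drift" in reports:
                reliable = reliable + reports["drift"].reliable
            joined = sway_panel if drift_panel is None else sway_panel.join(drift_panel)
            keep = [b for b in reliable if b in joined.values.columns]
            if keep:
                from swaymetrics.panel import BiomarkerPanel

                sub = BiomarkerPanel(
                    values=joined.values[keep], flags=joined.flags[keep], kind="combined"
                )
                corr = correlate(sub, cohort, targets, alpha=config.bh_alpha)
                corr.to_csv(out / "correlations.csv", index=False)
                record(out / "correlations.csv")

        stage = "age_band"
        if cohort is not None and (cohort["diagnosis"] == "HV").sum() >= 5:
            band = fit_age_band(sway_panel, cohort, config.age_band_biomarker)
            band_info = {
                "biomarker": config.age_band_biomarker,
                "slope": band.slope_,
                "intercept": band.intercept_,
                "resid_sd": band.resid_sd_,
                "n": band.n_,
                "level": band.level,
            }
            (out / "age_band.json").write_text(json.dumps(band_info, indent=2))
            record(out / "age_band.json")
            calls, fractions = call_abnormal(
                band, sway_panel, cohort, config.age_band_biomarker
            )
            fractions.to_csv(out / "abnormal_fractions.csv")
            record(out / "abnormal_fractions.csv")
            sizes = calls["diagnosis"].value_counts()
            big = sizes.index[sizes >= 2]
            if len(big) >= 2:
                pairwise = compare_groups(
                    calls.loc[calls["diagnosis"].isin(big), "residual"],
                    calls.loc[calls["diagnosis"].isin(big), "diagnosis"],
                    alpha=config.bh_alpha,
                )
                pairwise.to_csv(out / "group_comparisons.csv", index=False)
                record(out / "group_comparisons.csv")

        stage = "model"
        if config.run_models and cohort is not None:
            model_reports = []
            panels = {"sway": sway_panel, "drift": drift_panel}
            for feature_set, outcome in config.model_plan:
                if outcome not in cohort.columns:
                    continue
                if feature_set == "combined":
                    if drift_panel is None:
                        continue
                    panel = sway_panel.join(drift_panel)
                    rel = reports["sway"].reliable + reports.get(
                        "drift", reports["sway"]
                    ).reliable
                else:
                    panel = panels.get(feature_set)
                    if panel is None or feature_set not in reports:
                        continue
                    rel = reports[feature_set].reliable
                rel = [b for b in rel if b in panel.values.columns]
                if len(rel) < 2:
                    logger.warning(
                        "skipping %s/%s: fewer than 2 reliable biomarkers",
                        feature_set,
                        outcome,
                    )
                    continue
                subj = subject_values(panel)[rel]
                y = cohort.loc[subj.index.intersection(cohort.index), outcome]
                subj = subj.loc[y.index]
                split = cohort.loc[y.index, "split"]
                X_tr, y_tr = subj[split == "train"], y[split == "train"]
                X_va, y_va = subj[split == "validation"], y[split == "validation"]
                if len(X_tr) < 10 or len(X_va) < 3:
                    logger.warning(
                        "skipping %s/%s: too few subjects", feature_set, outcome
                    )
                    continue
                model = DisabilityScaleRegressor(random_state=config.seed).fit(X_tr, y_tr)
                report = validate_model(
                    model, X_tr, y_tr, X_va, y_va, outcome=outcome, feature_set=feature_set
                )
                model_reports.append(report.to_dict())
                logger.info(
                    "%s -> %s: %s (CV R^2 %.3f)",
                    feature_set,
                    outcome,
                    model.best_strategy_,
                    model.cv_r2_,
                )
            (out / "model_reports.json").write_text(
                json.dumps(model_reports, indent=2, default=float)
            )
            record(out / "model_reports.json")
            manifest["log"]["models"] = [
                (m["feature_set"], m["outcome"], m["strategy"]) for m in model_reports
            ]
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
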