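"""Synthetic accelerometer traces and cohorts with known ground truth.

Real sway recordings cannot ship with the package, so every downstream
stage is exercised on simulated data whose generating parameters are known
exactly.  The signal model is deliberately simple and analytically
tractable rather than biomechanically realistic:

* Horizontal (M-L, A-P) sway acceleration is a sum of sinusoids with a
  configurable line spectrum plus band-limited Gaussian noise (low-pass
  filtered at 10 Hz), scaled to a target standard deviation.  Stance
  difficulty multiplies that scale (eyes closed / feet together sway more
  than eyes open / feet apart).
* Gravity enters as a constant vertical component; a fixed per-subject
  device tilt rotates the whole vector series off vertical, which is what
  the calibration stage must undo.
* Subject-to-subject and trial-to-trial variability act multiplicatively
  on the sway scale (normal on the log10 scale), so the test-retest ICC of
  any log-amplitude biomarker is designed directly by the ratio
  between_sd^2 / (between_sd^2 + within_sd^2).
* Cohort outcomes (EDSS, CombiWISE, NeurEx and its subpanels) are linear
  in the latent sway/drift severities with age trends, diagnosis-group
  offsets and additive noise, then clipped/rounded to their scales.

All randomness derives from one seed expanded into per-(subject, trial,
condition) substreams via ``numpy.random.SeedSequence`` keyed on the
indices, so any single trace is reproducible independent of generation
order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from swaymetrics.ingest import RawTrace, SWAY_CONDITIONS, DRIFT_CONDITIONS

_COND_CODE = {"EO-FA": 0, "EO-FT": 1, "EC-FT": 2, "left": 3, "right": 4}

GROUPS = ("HV", "NIND", "OIND", "MS-RR", "MS-SP", "MS-PP")


@dataclass
class SwaySimParams:
    """Parameters of the accelerometer trace generator."""

    subject_count: int = 20
    trials_per_subject: int = 2
    sample_rate: float = 50.0
    duration: float = 9.5
    gravity_magnitude: float = 9.81
    #: fixed device tilt off vertical per subject (deg); azimuth is random
    tilt_angle_deg: float = 5.0
    #: baseline horizontal sway std, m/s^2 (typical quiet-stance trunk values)
    sigma_ml: float = 0.03
    sigma_ap: float = 0.04
    #: (frequency Hz, relative power) sinusoidal lines of the sway spectrum
    spectral_components: tuple = ((0.3, 1.0), (0.7, 0.6), (1.2, 0.3))
    #: fraction of horizontal variance carried by band-limited noise
    noise_fraction: float = 0.3
    #: low-pass edge for the noise component, Hz
    lowpass_hz: float = 10.0
    #: stance-difficulty multipliers on the sway scale
    condition_factors: dict = field(
        default_factory=lambda: {
            "EO-FA": 1.0,
            "EO-FT": 1.3,
            "EC-FT": 1.8,
            "left": 1.0,
            "right": 1.0,
        }
    )
    #: subject-level and trial-level sd of the log10 sway scale (designs ICC)
    between_subject_sd: float = 0.15
    within_subject_sd: float = 0.05
    #: relative vertical noise (fraction of the horizontal scale)
    vertical_noise_fraction: float = 0.2
    rng_seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.subject_count < 1 or self.trials_per_subject < 1:
            raise ValueError("subject_count and trials_per_subject must be positive")
        if min(self.between_subject_sd, self.within_subject_sd, self.noise_fraction) < 0:
            raise ValueError("variance components must be non-negative")
        nyq = self.sample_rate / 2.0
        for f, p in self.spectral_components:
            if not 0 < f < nyq:
                raise ValueError(f"spectral component at {f} Hz outside (0, Nyquist)")
            if p < 0:
                raise ValueError("spectral component powers must be non-negative")

    @property
    def designed_icc(self) -> float:
        """Test-retest ICC implied by the log-scale variance components."""
        b2 = self.between_subject_sd**2
        w2 = self.within_subject_sd**2
        if b2 + w2 == 0:
            return float("nan")
        return b2 / (b2 + w2)


@dataclass
class CohortSimParams:
    """Parameters linking latent sway/drift severity to cohort outcomes."""

    group_proportions: dict = field(
        default_factory=lambda: {
            "HV": 0.25,
            "NIND": 0.15,
            "OIND": 0.08,
            "MS-RR": 0.28,
            "MS-SP": 0.14,
            "MS-PP": 0.10,
        }
    )
    age_range: dict = field(
        default_factory=lambda: {g: (20.0, 70.0) for g in GROUPS}
    )
    #: log10-amplitude increase per year of age (applies to every group)
    age_slope: float = 0.006
    #: reference age at which the age term vanishes
    age_ref: float = 45.0
    #: diagnosis-group shifts of the log10 sway scale
    group_offsets: dict = field(
        default_factory=lambda: {
            "HV": 0.0,
            "NIND": 0.06,
            "OIND": 0.10,
            "MS-RR": 0.15,
            "MS-SP": 0.30,
            "MS-PP": 0.38,
        }
    )
    #: drift severity = drift_group_scale * group offset + own noise
    drift_group_scale: float = 0.6
    #: outcome -> (intercept, sway loading, drift loading)
    outcome_loadings: dict = field(
        default_factory=lambda: {
            "EDSS": (1.0, 6.0, 3.0),
            "CombiWISE": (12.0, 70.0, 35.0),
            "NeurEx": (15.0, 160.0, 80.0),
        }
    )
    noise_sd: dict = field(
        default_factory=lambda: {
            "EDSS": 0.6,
            "CombiWISE": 5.0,
            "NeurEx": 12.0,
            "panel": 0.6,
        }
    )
    #: NeurEx subpanel (intercept, severity loading) triples per latent
    sway_panel_loadings: tuple = ((1.0, 9.0), (0.5, 6.0), (0.5, 5.0))
    drift_panel_loadings: tuple = ((0.8, 5.0), (0.5, 4.0), (0.4, 3.0))
    fraction_female: float = 0.5
    fraction_right_handed: float = 0.9
    subject_count: int | None = None
    rng_seed: int = 0

    def __post_init__(self):
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions sum to {total}, expected 1")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float) -> np.ndarray:
    """Unit-std Gaussian noise low-passed at ``cutoff`` Hz."""
    white = rng.standard_normal(n)
    if cutoff < fs / 2.0:
        b, a = sps.butter(4, cutoff / (fs / 2.0), btype="low")
        white = sps.filtfilt(b, a, white)
    sd = white.std()
    return white / sd if sd > 0 else white


def _horizontal_signal(
    rng: np.random.Generator,
    n: int,
    fs: float,
    components,
    noise_fraction: float,
    lowpass_hz: float,
) -> np.ndarray:
    """Unit-variance sway waveform: spectral lines + band-limited noise."""
    t = np.arange(n) / fs
    x = np.zeros(n)
    total_power = sum(p for _, p in components)
    det_fraction = 1.0 - noise_fraction
    if total_power > 0 and det_fraction > 0:
        for f, p in components:
            amp = np.sqrt(2.0 * det_fraction * p / total_power)
            phase = rng.uniform(0, 2 * np.pi)
            x += amp * np.sin(2 * np.pi * f * t + phase)
    if noise_fraction > 0:
        x += np.sqrt(noise_fraction) * _bandlimited_noise(rng, n, fs, lowpass_hz)
    return x


def _tilt_rotation(angle_deg: float, azimuth_rad: float) -> np.ndarray:
    """Rotation by ``angle_deg`` about the horizontal axis at ``azimuth_rad``."""
    theta = np.deg2rad(angle_deg)
    a = np.array([np.cos(azimuth_rad), np.sin(azimuth_rad), 0.0])
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _subject_effects(params: SwaySimParams, subject_index: int) -> tuple[float, float, float]:
    """(log10 scale offset, tilt angle, tilt azimuth) for one subject."""
    rng = _rng(params.rng_seed, subject_index)
    offset = rng.normal(0.0, params.between_subject_sd)
    azimuth = rng.uniform(0, 2 * np.pi)
    return offset, params.tilt_angle_deg, azimuth


def simulate_trace(
    params: SwaySimParams,
    subject_index: int,
    trial_index: int,
    condition: str,
    subject_log_offset: float | None = None,
) -> RawTrace:
    """Generate one raw tri-axial trace for (subject, trial, condition).

    ``subject_log_offset`` overrides the internally drawn subject-level
    log10 scale deviation (used by :func:`simulate_cohort`, where that
    deviation carries age trends and group offsets).  Identical arguments
    and seed yield bit-identical traces.
    """
    if condition not in _COND_CODE:
        raise ValueError(f"unknown condition label: {condition!r}")
    if not (0 <= subject_index < params.subject_count):
        raise IndexError(f"subject_index {subject_index} out of bounds")
    if not (0 <= trial_index < params.trials_per_subject):
        raise IndexError(f"trial_index {trial_index} out of bounds")

    n = int(round(params.sample_rate * params.duration))
    t = np.arange(n) / params.sample_rate

    drawn_offset, tilt_deg, azimuth = _subject_effects(params, subject_index)
    if subject_log_offset is None:
        subject_log_offset = drawn_offset
    trial_rng = _rng(params.rng_seed, subject_index, 1000 + trial_index)
    trial_offset = trial_rng.normal(0.0, params.within_subject_sd)
    scale = 10.0 ** (subject_log_offset + trial_offset)
    factor = params.condition_factors.get(condition, 1.0)

    cond_rng = _rng(
        params.rng_seed, subject_index, trial_index, _COND_CODE[condition]
    )
    sigma_ml = params.sigma_ml * factor * scale
    sigma_ap = params.sigma_ap * factor * scale
    ml = sigma_ml * _horizontal_signal(
        cond_rng, n, params.sample_rate, params.spectral_components,
        params.noise_fraction, params.lowpass_hz,
    )
    ap = sigma_ap * _horizontal_signal(
        cond_rng, n, params.sample_rate, params.spectral_components,
        params.noise_fraction, params.lowpass_hz,
    )
    sigma_v = params.vertical_noise_fraction * 0.5 * (sigma_ml + sigma_ap)
    vert = np.full(n, params.gravity_magnitude)
    if sigma_v > 0:
        vert = vert + sigma_v * _bandlimited_noise(
            cond_rng, n, params.sample_rate, params.lowpass_hz
        )

    truth = np.stack([ml, ap, vert], axis=1)
    measured = truth @ _tilt_rotation(tilt_deg, azimuth).T

    test = "sway" if condition in SWAY_CONDITIONS else "drift"
    return RawTrace(
        subject_id=f"S{subject_index:04d}",
        trial_id=f"T{trial_index + 1}",
        test=test,
        condition=condition,
        t=t,
        ax=measured[:, 0],
        ay=measured[:, 1],
        az=measured[:, 2],
    )


def neurex_sway_composite(panel_scores) -> float:
    """Balance-relevant examination composite: sqrt of the summed panel scores."""
    scores = np.asarray(panel_scores, dtype=float)
    if np.any(scores < 0):
        raise ValueError("panel scores must be non-negative")
    return float(np.sqrt(scores.sum()))


def _round_half_steps(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x) * 2.0) / 2.0


def simulate_cohort_table(
    sway: SwaySimParams, cohort: CohortSimParams
) -> tuple[pd.DataFrame, dict]:
    """Draw demographics, latent severities and clipped outcomes (no traces).

    Returns the cohort table indexed by subject_id and a ground-truth dict
    recording every latent quantity needed by recovery tests.
    """
    if cohort.subject_count is not None and cohort.subject_count != sway.subject_count:
        raise ValueError(
            f"inconsistent subject counts: sway has {sway.subject_count}, "
            f"cohort has {cohort.subject_count}"
        )
    n = sway.subject_count
    rng = _rng(cohort.rng_seed, 900001)

    groups = rng.choice(
        list(cohort.group_proportions), size=n, p=list(cohort.group_proportions.values())
    )
    ages = np.array(
        [rng.uniform(*cohort.age_range[g]) for g in groups]
    )
    sex = np.where(rng.random(n) < cohort.fraction_female, "F", "M")
    height = np.where(sex == "F", 165.0, 178.0) + rng.normal(0, 7, n)
    weight = np.where(sex == "F", 68.0, 82.0) + rng.normal(0, 12, n)
    dominance = np.where(rng.random(n) < cohort.fraction_right_handed, "right", "left")

    offsets = np.array([cohort.group_offsets[g] for g in groups])
    sev_sway = offsets + rng.normal(0, sway.between_subject_sd, n)
    sev_drift = cohort.drift_group_scale * offsets + rng.normal(
        0, sway.between_subject_sd, n
    )

    table = pd.DataFrame(
        {
            "age": ages,
            "sex": sex,
            "height": height,
            "weight": weight,
            "dominance": dominance,
            "diagnosis": groups,
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id"),
    )

    for name, (b0, b_sway, b_drift) in cohort.outcome_loadings.items():
        noise = rng.normal(0, cohort.noise_sd.get(name, 0.0), n)
        latent = b0 + b_sway * sev_sway + b_drift * sev_drift + noise
        if name == "EDSS":
            table[name] = np.clip(_round_half_steps(latent), 0.0, 10.0) + 0.0
        elif name == "CombiWISE":
            table[name] = np.clip(latent, 0.0, 100.0)
        else:
            table[name] = np.maximum(latent, 0.0)

    # NeurEx subpanels: three balance-relevant scores -> sqrt-sum composite
    panel_sd = cohort.noise_sd.get("panel", 0.0)
    sway_panels = []
    for j, (a, b) in enumerate(cohort.sway_panel_loadings):
        score = np.maximum(a + b * sev_sway + rng.normal(0, panel_sd, n), 0.0)
        table[f"sway_panel_{j + 1}"] = score
        sway_panels.append(score)
    table["NeurEx Postural Sway"] = np.sqrt(np.sum(sway_panels, axis=0))

    # Pronator drift: per-hand subsystem scores summed over both hands
    drift_total = np.zeros(n)
    cerebellar_dom = None
    for hand in ("dom", "ndom"):
        hand_sev = sev_drift if hand == "dom" else 0.8 * sev_drift
        for j, (a, b) in enumerate(cohort.drift_panel_loadings):
            score = np.maximum(a + b * hand_sev + rng.normal(0, panel_sd, n), 0.0)
            drift_total += score
            if hand == "dom" and j == 1:  # cerebellar subsystem, dominant hand
                cerebellar_dom = score
    table["NeurEx Pronator Drift"] = drift_total
    table["NeurEx Cerebellar Dom"] = cerebellar_dom

    ground_truth = {
        "severity_sway": dict(zip(table.index, map(float, sev_sway))),
        "severity_drift": dict(zip(table.index, map(float, sev_drift))),
        "group_offsets": dict(cohort.group_offsets),
        "age_slope": cohort.age_slope,
        "age_ref": cohort.age_ref,
        "outcome_loadings": {k: list(v) for k, v in cohort.outcome_loadings.items()},
        "between_subject_sd": sway.between_subject_sd,
        "within_subject_sd": sway.within_subject_sd,
        "designed_icc": sway.designed_icc,
    }
    return table, ground_truth


def simulate_cohort(
    sway: SwaySimParams, cohort: CohortSimParams
) -> tuple[list[RawTrace], pd.DataFrame, dict]:
    """Full study simulation: traces, cohort table and ground truth.

    Each subject's log10 sway scale deviation combines the age trend, the
    diagnosis-group offset and subject-level noise; trial-level noise is
    added inside the trace generator, so repeated trials realize the
    designed test-retest ICC.  Drift-hand traces use the drift severity.
    """
    table, truth = simulate_cohort_table(sway, cohort)
    traces: list[RawTrace] = []
    for i, subject_id in enumerate(table.index):
        age_term = cohort.age_slope * (table.loc[subject_id, "age"] - cohort.age_ref)
        off_sway = age_term + truth["severity_sway"][subject_id]
        off_drift = age_term + truth["severity_drift"][subject_id]
        for trial in range(sway.trials_per_subject):
            for cond in SWAY_CONDITIONS:
                traces.append(
                    simulate_trace(sway, i, trial, cond, subject_log_offset=off_sway)
                )
            for cond in DRIFT_CONDITIONS:
                traces.append(
                    simulate_trace(sway, i, trial, cond, subject_log_offset=off_drift)
                )
    truth["subject_log_offset_sway"] = {
        s: float(
            cohort.age_slope * (table.loc[s, "age"] - cohort.age_ref)
            + truth["severity_sway"][s]
        )
        for s in table.index
    }
    return traces, table, truth


def simulate_biomarker_panel(
    n_subjects: int,
    true_icc,
    n_trials: int = 2,
    seed: int = 0,
    columns=None,
):
    """Panel of log-scale biomarker values with designed per-column ICC.

    Column j is ``sqrt(icc_j) * subject + sqrt(1 - icc_j) * noise`` with
    unit total variance, so its population test-retest ICC is exactly
    ``true_icc[j]``.  Used to validate the reliability screen against
    ground truth without simulating traces.
    """
    from swaymetrics.panel import BiomarkerPanel, FLAG_OK

    icc = np.asarray(true_icc, dtype=float)
    if np.any((icc < 0) | (icc > 1)):
        raise ValueError("true ICC values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    subj = rng.standard_normal((n_subjects, 1, len(icc)))
    noise = rng.standard_normal((n_subjects, n_trials, len(icc)))
    vals = np.sqrt(icc) * subj + np.sqrt(1.0 - icc) * noise
    index = pd.MultiIndex.from_product(
        [[f"S{i:04d}" for i in range(n_subjects)], [f"T{t + 1}" for t in range(n_trials)]],
        names=["subject_id", "trial_id"],
    )
    if columns is None:
        columns = [f"BM{j:02d}" for j in range(len(icc))]
    values = pd.DataFrame(vals.reshape(n_subjects * n_trials, len(icc)), index=index, columns=columns)
    flags = pd.DataFrame(FLAG_OK, index=index, columns=columns)
    return BiomarkerPanel(values=values, flags=flags, kind="synthetic")


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path)


def write_ground_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)


def params_from_dict(d: dict) -> SwaySimParams:
    """Build SwaySimParams from a (YAML-loaded) mapping, ignoring extras."""
    names = {f.name for f in dataclasses.fields(SwaySimParams)}
    return SwaySimParams(**{k: v for k, v in d.items() if k in names})
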