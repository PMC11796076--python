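"""Reading, trimming and gravity-calibrating raw accelerometer traces.

A balance or drift test yields a short (~9.5 s, nominal 50 Hz) tri-axial
acceleration series in the device frame.  Before sway features can be
computed, the series is trimmed to a fixed 9 s window and rotated so the mean
acceleration vector (dominated by gravity) points along the vertical axis;
the two horizontal components after rotation are the medio-lateral (M-L) and
antero-posterior (A-P) sway accelerations, and their per-sample radial
combination is the "Net" series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NOMINAL_RATE_HZ = 50.0
#: maximum tolerated deviation of the median sample interval from nominal
JITTER_TOLERANCE = 0.20

TRACE_COLUMNS = ["subject_id", "trial_id", "test", "condition", "t_s", "ax", "ay", "az"]

SWAY_CONDITIONS = ("EO-FA", "EO-FT", "EC-FT")
DRIFT_CONDITIONS = ("left", "right")
ALL_CONDITIONS = SWAY_CONDITIONS + DRIFT_CONDITIONS


@dataclass
class RawTrace:
    """One test's tri-axial accelerometer samples in the device frame."""

    subject_id: str
    trial_id: str
    test: str  # "sway" or "drift"
    condition: str  # EO-FA / EO-FT / EC-FT / left / right
    t: np.ndarray  # seconds, strictly increasing
    ax: np.ndarray  # m/s^2, device axes
    ay: np.ndarray
    az: np.ndarray
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("axis series must all have the same length as t")
        if self.condition not in ALL_CONDITIONS:
            raise ValueError(f"unknown condition label: {self.condition!r}")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError(
                    f"timestamps not strictly increasing for "
                    f"{self.subject_id}/{self.trial_id}/{self.condition}"
                )
            med = float(np.median(dt))
            if abs(med - 1.0 / NOMINAL_RATE_HZ) > JITTER_TOLERANCE / NOMINAL_RATE_HZ:
                self.flags.append("irregular_sampling")
        else:
            self.flags.append("short")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sample_rate(self) -> float:
        """Nominal sample rate inferred from the median interval, in Hz."""
        if len(self.t) < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        """Nominal duration n / rate in seconds."""
        return len(self.t) / self.sample_rate

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.trial_id, self.test, self.condition)


@dataclass
class CalibratedTrace:
    """M-L, A-P and Net (radial) acceleration after gravity/tilt calibration.

    ``aml`` and ``aap`` are zero-mean by construction; ``anet[i]`` is the
    per-sample radial magnitude ``sqrt(aml[i]**2 + aap[i]**2)``.
    """

    aml: np.ndarray
    aap: np.ndarray
    anet: np.ndarray
    sample_rate: float
    duration: float
    provenance: tuple  # (subject_id, trial_id, test, condition)

    @property
    def subject_id(self) -> str:
        return self.provenance[0]

    @property
    def trial_id(self) -> str:
        return self.provenance[1]

    @property
    def test(self) -> str:
        return self.provenance[2]

    @property
    def condition(self) -> str:
        return self.provenance[3]


def read_traces(path) -> list[RawTrace]:
    """Read a long-format trace CSV into one :class:`RawTrace` per group.

    The CSV needs columns ``subject_id, trial_id, test, condition, t_s, ax,
    ay, az``.  Rows are sorted by time within each (subject, trial, test,
    condition) group, so shuffled files produce the same traces as sorted
    ones.  Groups with non-monotone timestamps (after sorting: duplicate
    times) are rejected with a warning rather than raising.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty trace file: {path}")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} is missing columns: {missing}")

    traces = []
    for key, g in df.groupby(["subject_id", "trial_id", "test", "condition"], sort=True):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy(dtype=float)
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            warnings.warn(f"non-monotone timestamps in group {key}; group skipped")
            continue
        traces.append(
            RawTrace(
                subject_id=str(key[0]),
                trial_id=str(key[1]),
                test=str(key[2]),
                condition=str(key[3]),
                t=t,
                ax=g["ax"].to_numpy(dtype=float),
                ay=g["ay"].to_numpy(dtype=float),
                az=g["az"].to_numpy(dtype=float),
            )
        )
    return traces


def trim(trace: RawTrace, target_duration: float = 9.0) -> RawTrace:
    """Keep the last ``target_duration`` seconds of a trace.

    The surplus at the start of a recording most plausibly contains the
    subject's reaction to the start cue, so leading samples are dropped.
    ``round(target_duration * nominal rate)`` samples are retained; a trace
    shorter than the target raises.
    """
    if len(trace) < 2:
        raise ValueError(f"trace too short to trim: {trace.key}")
    rate = trace.sample_rate
    if trace.duration < target_duration - 1e-9:
        raise ValueError(
            f"trace {trace.key} has duration {trace.duration:.3f} s "
            f"< target {target_duration} s"
        )
    n_keep = int(round(target_duration * rate))
    if n_keep >= len(trace):
        return trace
    sl = slice(len(trace) - n_keep, None)
    return RawTrace(
        subject_id=trace.subject_id,
        trial_id=trace.trial_id,
        test=trace.test,
        condition=trace.condition,
        t=trace.t[sl],
        ax=trace.ax[sl],
        ay=trace.ay[sl],
        az=trace.az[sl],
    )


def _rotation_to_vertical(mean_vec: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ``mean_vec`` direction onto +z (Rodrigues)."""
    u = mean_vec / np.linalg.norm(mean_vec)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(u, z), -1.0, 1.0))
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # mean points straight down: flip about x
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    theta = np.arctan2(s, c)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def calibrate(trace: RawTrace, axis_map: tuple[str, str] = ("x", "y")) -> CalibratedTrace:
    """Tilt-correct a trimmed trace and split it into M-L / A-P / Net series.

    The mean acceleration vector over the trace defines the vertical; the
    minimal rotation taking it onto (0, 0, ||g||) is applied to every sample.
    ``axis_map`` names the two rotated device axes assigned to (M-L, A-P) —
    the default assumes the device is worn upright with its x axis lateral.
    Horizontal series are mean-subtracted so residual misalignment never
    leaks a DC offset into amplitude features.
    """
    samples = np.stack([trace.ax, trace.ay, trace.az], axis=1)
    mean_vec = samples.mean(axis=0)
    norm = np.linalg.norm(mean_vec)
    if norm < 1.0:
        raise ValueError(
            f"cannot determine vertical for {trace.key}: mean acceleration "
            f"magnitude {norm:.3f} m/s^2 is too small"
        )
    R = _rotation_to_vertical(mean_vec)
    rotated = samples @ R.T
    axis_index = {"x": 0, "y": 1, "z": 2}
    iml, iap = axis_index[axis_map[0]], axis_index[axis_map[1]]
    aml = rotated[:, iml]
    aap = rotated[:, iap]
    aml = aml - aml.mean()
    aap = aap - aap.mean()
    anet = np.hypot(aml, aap)
    return CalibratedTrace(
        aml=aml,
        aap=aap,
        anet=anet,
        sample_rate=trace.sample_rate,
        duration=trace.duration,
        provenance=trace.key,
    )


def write_traces_csv(traces: list[RawTrace], path) -> None:
    """Write traces back to the long CSV schema accepted by read_traces."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": tr.subject_id,
                    "trial_id": tr.trial_id,
                    "test": tr.test,
                    "condition": tr.condition,
                    "t_s": tr.t,
                    "ax": tr.ax,
                    "ay": tr.ay,
                    "az": tr.az,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
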