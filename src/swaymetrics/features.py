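"""Time- and frequency-domain sway measurements.

Four measurement families are computed from each calibrated acceleration
series:

* RMS — root mean square acceleration, sqrt(mean(a_i^2)): sway amplitude.
* Jerk — integral of the squared time derivative of acceleration,
  approximated by a forward first difference and rectangle rule:
  sum_i ((a_{i+1} - a_i)/dt)^2 * dt.  Net Jerk averages the M-L and A-P
  jerk integrals: (Jerk_ML + Jerk_AP) / 2.
* Spectral centroid (SC) — first moment mu_1 of the in-band power spectrum,
  the PSD-weighted mean frequency of sway.
* Spectral spread (SS) — mu_2, the PSD-weighted standard deviation of
  frequency about the centroid.

Spectra are one-sided periodograms (rectangular window, mean removed) so
that the full-band integral of the PSD equals the series variance
(Parseval).  Spectral moments are restricted to a configurable band,
defaulting to 0.15-10 Hz: the lower edge excludes residual drift/DC, the
upper edge bounds voluntary and tremor-range sway at 50 Hz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

#: default spectral-moment band edges (b1, b2) in Hz
DEFAULT_BAND = (0.15, 10.0)

MEASURES = ("RMS", "Jerk", "SC", "SS")
AXES = ("ML", "AP", "Net")


@dataclass
class FrequencySpectrum:
    """In-band slice of a one-sided power spectral density.

    f: frequency bins in Hz, strictly increasing; s: PSD values, >= 0;
    band: the (b1, b2) edges the bins were restricted to.
    """

    f: np.ndarray
    s: np.ndarray
    band: tuple[float, float]

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if len(self.f) != len(self.s):
            raise ValueError("f and s must have equal length")
        if np.any(self.s < 0):
            raise ValueError("PSD values must be non-negative")
        if len(self.f) > 1 and np.any(np.diff(self.f) <= 0):
            raise ValueError("frequency bins must be strictly increasing")


def rms(series) -> float:
    """Root mean square of a series: sqrt((1/N) sum a_i^2)."""
    a = np.asarray(series, dtype=float)
    if a.size == 0:
        raise ValueError("rms of an empty series is undefined")
    return float(np.sqrt(np.mean(a**2)))


def jerk(series, sample_rate: float) -> float:
    """Integrated squared derivative of acceleration.

    Discretizes integral_0^T (dAcc/dt)^2 dt with a forward first difference
    and rectangle rule; units (m/s^3)^2 * s.  Invariant to additive
    constants and quadratic in amplitude.
    """
    a = np.asarray(series, dtype=float)
    if a.size < 2:
        raise ValueError("jerk needs at least 2 samples")
    dt = 1.0 / sample_rate
    d = np.diff(a) / dt
    return float(np.sum(d**2) * dt)


def net_jerk(aml, aap, sample_rate: float) -> float:
    """Net jerk over both horizontal axes: (Jerk_ML + Jerk_AP) / 2."""
    aml = np.asarray(aml, dtype=float)
    aap = np.asarray(aap, dtype=float)
    if aml.shape != aap.shape:
        raise ValueError("M-L and A-P series must have equal length")
    return 0.5 * (jerk(aml, sample_rate) + jerk(aap, sample_rate))


def power_spectrum(series, sample_rate: float, band: tuple[float, float] = DEFAULT_BAND) -> FrequencySpectrum:
    """One-sided periodogram of a mean-subtracted series, restricted to band.

    Rectangular window, no segment averaging: a 9 s x 50 Hz test gives only
    450 samples, too few to subdivide without destroying low-frequency
    resolution.  PSD scaling is chosen so sum(s) * df equals the series
    variance over the full band.
    """
    a = np.asarray(series, dtype=float)
    if a.size < 8:
        raise ValueError("power_spectrum needs at least 8 samples")
    b1, b2 = band
    nyquist = sample_rate / 2.0
    if not (0 <= b1 < b2 <= nyquist + 1e-12):
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyquist}]")
    f, s = signal.periodogram(
        a, fs=sample_rate, window="boxcar", detrend="constant", scaling="density"
    )
    mask = (f >= b1) & (f <= b2)
    if not np.any(mask):
        raise ValueError(f"band {band} contains no frequency bins")
    return FrequencySpectrum(f=f[mask], s=s[mask], band=(b1, b2))


def spectral_centroid(spec: FrequencySpectrum) -> float:
    """PSD-weighted mean frequency mu_1 = sum(f_k s_k) / sum(s_k), in Hz.

    Returns NaN when the in-band power is zero (flat signal): the centroid
    of an empty spectrum is undefined and is propagated as missing.
    """
    total = float(np.sum(spec.s))
    if total <= 0:
        return float("nan")
    return float(np.sum(spec.f * spec.s) / total)


def spectral_spread(spec: FrequencySpectrum) -> float:
    """PSD-weighted frequency standard deviation mu_2 about the centroid, Hz."""
    total = float(np.sum(spec.s))
    if total <= 0:
        return float("nan")
    mu1 = float(np.sum(spec.f * spec.s) / total)
    return float(np.sqrt(np.sum((spec.f - mu1) ** 2 * spec.s) / total))


def trace_features(cal, band: tuple[float, float] = DEFAULT_BAND) -> dict[tuple[str, str], float]:
    """All (measure, axis) feature values for one calibrated trace.

    Sway traces yield the full 4 measures x 3 axes grid; the Net jerk uses
    the two-axis formula, and Net SC/SS are moments of the radial series'
    spectrum.  Returns a dict keyed by (measure, axis).
    """
    fs = cal.sample_rate
    out: dict[tuple[str, str], float] = {}
    series = {"ML": cal.aml, "AP": cal.aap, "Net": cal.anet}
    for axis, a in series.items():
        out[("RMS", axis)] = rms(a)
        spec = power_spectrum(a - np.mean(a), fs, band)
        out[("SC", axis)] = spectral_centroid(spec)
        out[("SS", axis)] = spectral_spread(spec)
    out[("Jerk", "ML")] = jerk(cal.aml, fs)
    out[("Jerk", "AP")] = jerk(cal.aap, fs)
    out[("Jerk", "Net")] = net_jerk(cal.aml, cal.aap, fs)
    return out
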