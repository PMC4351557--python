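"""Ensemble power spectra, log-log slope fits, plateau detection, aging.

The central diagnostic is the ensemble-averaged one-sided periodogram of
mean-subtracted series.  1/f noise appears as S(f) ~ f^(-beta) over a band
above a low-frequency plateau; the plateau onset (transition frequency f_t)
reflects the exponential cutoff of the residence-time distribution.  Aging
— dependence of the PSD magnitude on total measurement time — is checked
by recomputing the ensemble PSD on nested prefixes of the data: processes
with finite mean sojourn times are stationary and their spectra coincide.

Frequencies are handled internally in ps^-1 (1 ps^-1 = 10^12 Hz = 1 THz;
the reference transition frequency 0.3 GHz is 3e-4 ps^-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

PS_INV_TO_HZ = 1e12


@dataclass
class PowerSpectrum:
    """One-sided spectral density on a positive frequency grid (ps^-1)."""

    freqs: np.ndarray
    power: np.ndarray
    n_ensemble: int = 1
    measurement_time: float = float("nan")

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if self.freqs.size and (np.any(np.diff(self.freqs) <= 0) or self.freqs[0] <= 0):
            raise ValueError("freqs must be strictly increasing and positive")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def freqs_hz(self) -> np.ndarray:
        return self.freqs * PS_INV_TO_HZ

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])


@dataclass
class SlopeFit:
    """Least-squares log-log slope: S(f) ~ f^(-beta) over [f_lo, f_hi]."""

    beta: float
    f_lo: float
    f_hi: float
    stderr: float
    f_t: float | None = None


def periodogram(series, dt: float = 1.0) -> PowerSpectrum:
    """Mean-subtracted one-sided periodogram of a single series.

    S(f_k) for k = 1..N/2 with density scaling (units^2 * ps), so that
    sum_k S(f_k) * df equals the series variance exactly (Parseval).
    """
    x = np.asarray(getattr(series, "values", getattr(series, "states", series)), dtype=float)
    dt = float(getattr(series, "dt", dt))
    if x.size < 4:
        raise ValueError("series too short for a periodogram (need >= 4 frames)")
    freqs, power = signal.periodogram(
        x, fs=1.0 / dt, window="boxcar", detrend="constant", scaling="density"
    )
    return PowerSpectrum(freqs[1:], power[1:], n_ensemble=1, measurement_time=x.size * dt)


def ensemble_psd(series_list: Sequence, dt: float = 1.0) -> PowerSpectrum:
    """Pointwise mean of individual periodograms over an ensemble."""
    if len(series_list) == 0:
        raise ValueError("empty ensemble")
    spectra = [periodogram(s, dt) for s in series_list]
    n0 = spectra[0].freqs.size
    if any(sp.freqs.size != n0 for sp in spectra):
        raise ValueError("all ensemble members must have equal length")
    power = np.mean([sp.power for sp in spectra], axis=0)
    return PowerSpectrum(
        spectra[0].freqs,
        power,
        n_ensemble=len(spectra),
        measurement_time=spectra[0].measurement_time,
    )


def log_rebin(spectrum: PowerSpectrum, bins_per_decade: int = 4) -> PowerSpectrum:
    """Average the spectrum into logarithmically spaced frequency bins.

    Equalizes the leverage of the (linearly dense) high-frequency bins in
    log-log regression.  Bin centers are the geometric means of the member
    frequencies; empty bins are dropped.
    """
    f, p = spectrum.freqs, spectrum.power
    lo, hi = np.log10(f[0]), np.log10(f[-1])
    n_bins = max(int(np.ceil((hi - lo) * bins_per_decade)), 1)
    edges = np.logspace(lo, hi, n_bins + 1)
    edges[-1] *= 1 + 1e-12
    idx = np.digitize(f, edges) - 1
    centers, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if not np.any(sel):
            continue
        centers.append(np.exp(np.mean(np.log(f[sel]))))
        means.append(np.mean(p[sel]))
    return PowerSpectrum(
        np.asarray(centers),
        np.asarray(means),
        n_ensemble=spectrum.n_ensemble,
        measurement_time=spectrum.measurement_time,
    )


def fit_loglog_slope(
    spectrum: PowerSpectrum,
    f_lo: float,
    f_hi: float,
    bins_per_decade: int = 4,
    f_t: float | None = None,
) -> SlopeFit:
    """Fit beta in S(f) ~ f^(-beta) by least squares over log-spaced bins.

    Raw (f, S) points inside the band are log-transformed and averaged
    within quarter-decade bins before the regression, equalizing the
    leverage of the linearly dense high-frequency bins; an exact power law
    is recovered to machine precision.
    """
    if not f_lo < f_hi:
        raise ValueError("f_lo must be < f_hi")
    sel = (spectrum.freqs >= f_lo) & (spectrum.freqs <= f_hi) & (spectrum.power > 0)
    if np.count_nonzero(sel) < 3:
        raise ValueError("fewer than 3 usable frequency bins in the fit band")
    lf = np.log10(spectrum.freqs[sel])
    lp = np.log10(spectrum.power[sel])
    n_bins = max(int(np.ceil((lf[-1] - lf[0]) * bins_per_decade)), 1)
    edges = np.linspace(lf[0], lf[-1] * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(lf, edges) - 1, 0, n_bins - 1)
    x = np.array([lf[idx == b].mean() for b in range(n_bins) if np.any(idx == b)])
    y = np.array([lp[idx == b].mean() for b in range(n_bins) if np.any(idx == b)])
    if x.size < 3:
        x, y = lf, lp
    res = stats.linregress(x, y)
    return SlopeFit(beta=-res.slope, f_lo=f_lo, f_hi=f_hi, stderr=res.stderr, f_t=f_t)


def detect_transition(
    spectrum: PowerSpectrum, bins_per_decade: int = 8
) -> float | None:
    """Locate the plateau-to-power-law transition frequency, if any.

    Fits a continuous two-segment model in log-log space — a flat level c
    below the breakpoint, a line of free slope above — by least squares
    over candidate breakpoints on the log-rebinned grid, and keeps the
    breakpoint only if the segmented model beats a single straight line on
    AIC.  Returns the transition frequency (ps^-1) or ``None``.
    """
    f_span = spectrum.freqs[-1] / spectrum.freqs[0]
    if f_span < 100:
        raise ValueError("spectrum must span at least two decades in frequency")
    rb = log_rebin(spectrum, bins_per_decade)
    pos = rb.power > 0
    x = np.log10(rb.freqs[pos])
    y = np.log10(rb.power[pos])
    m = x.size
    if m < 6:
        return None
    # single-line reference
    res = stats.linregress(x, y)
    sse_line = float(np.sum((y - (res.intercept + res.slope * x)) ** 2))
    best = (np.inf, None)
    for k in range(2, m - 2):  # breakpoint candidates between bins
        xb = x[k]
        low, high = y[: k + 1], y[k + 1 :]
        u = x[k + 1 :] - xb  # > 0
        # minimize sum (low - c)^2 + sum (high - c - b u)^2 over (c, b)
        n1, n2 = low.size, high.size
        su, suu = np.sum(u), np.sum(u * u)
        sy2, syu = np.sum(high), np.sum(high * u)
        a11, a12, b1 = n1 + n2, su, np.sum(low) + sy2
        a22, b2 = suu, syu
        det = a11 * a22 - a12 * a12
        if det <= 0:
            continue
        c = (b1 * a22 - b2 * a12) / det
        bslope = (a11 * b2 - a12 * b1) / det
        sse = float(np.sum((low - c) ** 2) + np.sum((high - c - bslope * u) ** 2))
        if sse < best[0]:
            best = (sse, xb)
    if best[1] is None:
        return None
    eps = 1e-12
    aic_line = m * np.log(sse_line / m + eps) + 2 * 2
    aic_seg = m * np.log(best[0] / m + eps) + 2 * 4  # level, slope, breakpoint, +1
    if aic_seg >= aic_line:
        return None
    return float(10 ** best[1])


def high_frequency_band(
    spectrum: PowerSpectrum, f_t: float | None = None
) -> tuple[float, float]:
    """Default 1/f fit band: from 3x the plateau onset to Nyquist/4."""
    if f_t is None:
        f_t = detect_transition(spectrum)
    f_lo = 3.0 * f_t if f_t is not None else spectrum.freqs[0]
    f_hi = spectrum.nyquist / 4.0
    if not f_lo < f_hi:
        f_lo = spectrum.freqs[0]
    return float(f_lo), float(f_hi)


def aging_check(
    series_list: Sequence,
    dt: float,
    measurement_times: Sequence[float],
    bins_per_decade: int = 4,
) -> tuple[list[PowerSpectrum], float]:
    """Compare ensemble PSDs computed on nested prefixes of the data.

    For each measurement time t the ensemble PSD is computed on the first
    t/dt frames of every series.  The returned offset is the maximum over
    the common frequency band of |log10 S_t1(f) - log10 S_t2(f)| between
    smoothed (log-rebinned) spectra, over all pairs.  Stationary processes
    give offsets well below log10(2); aging processes do not.
    """
    arrays = [
        np.asarray(getattr(s, "values", getattr(s, "states", s)), dtype=float)
        for s in series_list
    ]
    n = arrays[0].size
    spectra = []
    for t in measurement_times:
        n_t = int(round(t / dt))
        if n_t > n:
            raise ValueError(f"measurement time {t} exceeds the data ({n * dt})")
        spectra.append(ensemble_psd([a[:n_t] for a in arrays], dt))
    if len(spectra) < 2:
        return spectra, 0.0
    smooth = [log_rebin(sp, bins_per_decade) for sp in spectra]
    f_lo = max(sp.freqs[0] for sp in smooth)
    f_hi = min(sp.freqs[-1] for sp in smooth)
    grid = np.logspace(np.log10(f_lo), np.log10(f_hi), 64)
    curves = [
        np.interp(np.log10(grid), np.log10(sp.freqs), np.log10(np.maximum(sp.power, 1e-300)))
        for sp in smooth
    ]
    max_offset = 0.0
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            max_offset = max(max_offset, float(np.max(np.abs(curves[i] - curves[j]))))
    return spectra, max_offset
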