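"""Signal utilities: differentiation, cross-correlation alignment, spectra.

``estimate_lag`` implements the offline synchronisation used to align two
recordings of the same movement (e.g. marker-derived acceleration vs IMU
acceleration during calibration jumps): the lag of the normalised
cross-correlation maximum.  Sign convention: a positive lag means the
*second* series is delayed with respect to the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.signal import welch

from .timeseries import TimeSeries

__all__ = [
    "SyncResult",
    "second_derivative",
    "estimate_lag",
    "psd",
    "spectral_centroid",
    "band_power_fraction",
]


@dataclass(frozen=True)
class SyncResult:
    """Lag estimate between two equally sampled series."""

    lag_samples: int
    lag_s: float
    peak_corr: float


def second_derivative(x: TimeSeries) -> TimeSeries:
    """Second time-derivative by central differences (second-order accurate
    one-sided stencils at the edges); exact for quadratics."""
    if x.n < 3:
        raise ValueError("need at least 3 samples to differentiate twice")
    d1 = np.gradient(x.values, x.dt_s, edge_order=2)
    d2 = np.gradient(d1, x.dt_s, edge_order=2)
    return TimeSeries(d2, x.fs_hz, t0_s=x.t0_s, channel=x.channel)


def _corr_at_lag(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Pearson correlation of the overlap when b is shifted back by lag."""
    if lag >= 0:
        x, y = a[: len(a) - lag] if lag else a, b[lag:]
    else:
        x, y = a[-lag:], b[: len(b) + lag]
    m = min(len(x), len(y))
    x, y = x[:m], y[:m]
    if m < 2:
        return -np.inf
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return -np.inf
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def estimate_lag(a: TimeSeries, b: TimeSeries, max_lag_s: float = 1.0) -> SyncResult:
    """Lag of the maximum of the normalised cross-correlation.

    Searches lags in ``[-max_lag_s, +max_lag_s]``; ties are broken toward
    the smallest absolute lag.  If ``b`` equals ``a`` delayed by ``L``
    samples, the reported lag is ``+L``.
    """
    if abs(a.fs_hz - b.fs_hz) > 1e-9 * a.fs_hz:
        raise ValueError("series must share the sampling rate")
    if np.std(a.values) == 0.0 or np.std(b.values) == 0.0:
        raise ValueError("zero-variance input; lag undefined")
    L = round(max_lag_s * a.fs_hz)
    if min(a.n, b.n) < 2 * L:
        raise ValueError(f"need at least {2 * L} samples of overlap for max_lag={max_lag_s} s")
    best_lag, best_corr = 0, -np.inf
    # visit lags in order of increasing |lag| so ties resolve to the smaller
    for mag in range(L + 1):
        for lag in ((mag,) if mag == 0 else (-mag, mag)):
            c = _corr_at_lag(a.values, b.values, lag)
            if c > best_corr:
                best_lag, best_corr = lag, c
    return SyncResult(lag_samples=best_lag, lag_s=best_lag / a.fs_hz,
                      peak_corr=float(np.clip(best_corr, -1.0, 1.0)))


def psd(x: TimeSeries, nperseg_s: float = 4.0) -> Tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (Hann window, 50% overlap).

    Returns ``(freqs_hz, power)`` with density scaling, so the integral of
    the PSD approximates the signal variance (Parseval check: within ~5%).
    """
    if x.duration_s < 2.0:
        raise ValueError("need at least 2 s of data for a meaningful PSD")
    nperseg = min(x.n, round(nperseg_s * x.fs_hz))
    f, p = welch(x.values, fs=x.fs_hz, window="hann", nperseg=nperseg,
                 noverlap=nperseg // 2, detrend="constant", scaling="density")
    return f, p


def spectral_centroid(freqs: np.ndarray, power: np.ndarray) -> float:
    """Power-weighted mean frequency, Hz."""
    total = np.sum(power)
    if total <= 0:
        raise ValueError("spectrum has no power")
    return float(np.sum(freqs * power) / total)


def band_power_fraction(freqs: np.ndarray, power: np.ndarray,
                        f_max_hz: float) -> float:
    """Fraction of total spectral power at frequencies <= ``f_max_hz``."""
    total = np.sum(power)
    if total <= 0:
        raise ValueError("spectrum has no power")
    return float(np.sum(power[freqs <= f_max_hz]) / total)
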