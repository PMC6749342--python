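"""Adaptive-oscillator estimator of quasi-periodic signals.

A pool of phase-locked oscillators learns the fundamental frequency, phase
and waveform of a quasi-periodic input (a segment elevation angle during
steady walking) and emits a zero-phase-lag prediction.  The residual
``e = y - y_hat`` is small while the input stays rhythmic and grows when the
rhythm is broken — it is the anomaly signal consumed by the threshold
detector.

State and update law (forward Euler at the signal's sample interval dt)::

    y_hat = alpha0 + sum_{i=1..N} [alpha_i * sin(i*phi) + beta_i * cos(i*phi)]
    e     = y - y_hat
    phi   <- phi + dt * (omega + k_P * e * cos(phi))
    omega <- clamp(omega + dt * k_P * e * cos(phi), omega_min, omega_max)
    alpha0  <- alpha0  + dt * k_A * e
    alpha_i <- alpha_i + dt * k_A * e * sin(i*phi)
    beta_i  <- beta_i  + dt * k_A * e * cos(i*phi)

where the coupling terms use the pre-update phase.  ``k_P`` couples the
residual into phase and frequency (through the fundamental only); ``k_A``
drives waveform learning.  Each harmonic carries a sine/cosine quadrature
pair: a single-quadrature basis spans only waveforms odd-symmetric in the
oscillator phase and would leave an irreducible residual on general gait
waveforms, defeating the zero-lag contract.  The frequency is clamped to a
physiological band so a long aperiodic transient (e.g. during a trip)
cannot collapse or blow up the oscillator.

An alternative "kernel" waveform backend replaces the Fourier series with a
normalised sum of von-Mises bumps over phase, ``y_hat = sum_j w_j psi_j(phi)
/ sum_j psi_j(phi)``, with weight updates ``w_j <- w_j + dt * k_A * e *
psi_j(phi) / sum(psi)``.  Both backends satisfy the same contract
(synchronised, zero-lag estimation); the Fourier backend is the default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "AOParams",
    "AOState",
    "TrackedRecord",
    "AONumericalError",
    "ao_init",
    "ao_step",
    "ao_track",
    "tracking_metrics",
]

_TWO_PI = 2.0 * np.pi


class AONumericalError(RuntimeError):
    """Raised when the forward-Euler update diverges (gain too large for dt)."""


@dataclass(frozen=True)
class AOParams:
    """Learning gains and structural parameters of the oscillator pool.

    ``k_P`` (phase learning gain) and ``k_A`` (amplitude learning gain) are
    the two tunables searched during calibration.  ``omega_init_rad_s``
    defaults to the fundamental of a 1.25-s stride; the clamp band
    [2*pi*0.3, 2*pi*2.5] rad/s covers cadences from very slow to running.
    """

    k_P: float
    k_A: float
    n_harmonics: int = 6
    omega_init_rad_s: float = _TWO_PI / 1.25
    omega_min_rad_s: float = _TWO_PI * 0.3
    omega_max_rad_s: float = _TWO_PI * 2.5
    backend: str = "fourier"
    n_kernels: int = 18

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k_P) and math.isfinite(self.k_A)):
            raise ValueError("learning gains must be finite")
        if self.k_P < 0 or self.k_A < 0:
            raise ValueError("learning gains must be non-negative")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not (0 < self.omega_min_rad_s < self.omega_max_rad_s):
            raise ValueError("require 0 < omega_min < omega_max")
        if self.backend not in ("fourier", "kernel"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "kernel" and self.n_kernels < 2:
            raise ValueError("n_kernels must be >= 2")


@dataclass
class AOState:
    """Evolving oscillator state.

    For the Fourier backend ``alpha``/``beta`` hold the sine/cosine
    coefficients (length ``n_harmonics`` each).  For the kernel backend
    ``alpha`` holds the kernel weights (length ``n_kernels``) and ``beta``
    is empty.
    """

    params: AOParams
    phi: float
    omega: float
    alpha0: float
    alpha: np.ndarray
    beta: np.ndarray
    y_hat: float
    e: float

    def copy(self) -> "AOState":
        return AOState(self.params, self.phi, self.omega, self.alpha0,
                       self.alpha.copy(), self.beta.copy(), self.y_hat, self.e)


def _kernel_centers_width(n_kernels: int) -> Tuple[np.ndarray, float]:
    centers = _TWO_PI * np.arange(n_kernels) / n_kernels
    # width such that a kernel decays to ~0.5 at its neighbour's centre
    h = math.log(2.0) / (1.0 - math.cos(_TWO_PI / n_kernels))
    return centers, h


def _waveform(state: AOState, phi: float) -> float:
    p = state.params
    if p.backend == "fourier":
        arg = np.arange(1, p.n_harmonics + 1) * phi
        return state.alpha0 + float(state.alpha @ np.sin(arg) + state.beta @ np.cos(arg))
    centers, h = _kernel_centers_width(p.n_kernels)
    psi = np.exp(h * (np.cos(phi - centers) - 1.0))
    return state.alpha0 + float(state.alpha @ psi) / float(psi.sum())


def ao_init(params: AOParams) -> AOState:
    """Fresh state: zero phase and waveform, frequency at ``omega_init``."""
    if not (params.omega_min_rad_s <= params.omega_init_rad_s <= params.omega_max_rad_s):
        raise ValueError("omega_init_rad_s outside the clamp bounds")
    if params.backend == "fourier":
        alpha, beta = np.zeros(params.n_harmonics), np.zeros(params.n_harmonics)
    else:
        alpha, beta = np.zeros(params.n_kernels), np.zeros(0)
    return AOState(params=params, phi=0.0, omega=params.omega_init_rad_s,
                   alpha0=0.0, alpha=alpha, beta=beta, y_hat=0.0, e=0.0)


def ao_step(state: AOState, y_t: float, dt: float) -> AOState:
    """Advance the oscillator by one sample (in place) and return the state.

    The stored ``y_hat`` and ``e`` are recomputed from the post-update state
    so that ``e`` is the residual actually fed to the downstream detector.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(y_t):
        raise ValueError("y_t must be finite")
    p = state.params
    phi, omega = state.phi, state.omega

    if p.backend == "fourier":
        arg = np.arange(1, p.n_harmonics + 1) * phi
        sin_b, cos_b = np.sin(arg), np.cos(arg)
        y_pre = state.alpha0 + float(state.alpha @ sin_b + state.beta @ cos_b)
        e = y_t - y_pre
        coupling = p.k_P * e * math.cos(phi)
        state.phi = (phi + dt * (omega + coupling)) % _TWO_PI
        state.omega = min(max(omega + dt * coupling, p.omega_min_rad_s), p.omega_max_rad_s)
        state.alpha0 += dt * p.k_A * e
        state.alpha += dt * p.k_A * e * sin_b
        state.beta += dt * p.k_A * e * cos_b
    else:
        centers, h = _kernel_centers_width(p.n_kernels)
        psi = np.exp(h * (np.cos(phi - centers) - 1.0))
        psi_sum = float(psi.sum())
        y_pre = state.alpha0 + float(state.alpha @ psi) / psi_sum
        e = y_t - y_pre
        coupling = p.k_P * e * math.cos(phi)
        state.phi = (phi + dt * (omega + coupling)) % _TWO_PI
        state.omega = min(max(omega + dt * coupling, p.omega_min_rad_s), p.omega_max_rad_s)
        # kernels absorb the offset themselves; alpha0 stays fixed
        state.alpha += dt * p.k_A * e * (psi / psi_sum)

    state.y_hat = _waveform(state, state.phi)
    state.e = y_t - state.y_hat
    if not (math.isfinite(state.phi) and math.isfinite(state.y_hat)
            and np.all(np.isfinite(state.alpha)) and np.all(np.isfinite(state.beta))
            and math.isfinite(state.alpha0)):
        raise AONumericalError(
            f"oscillator state diverged (k_P={p.k_P}, k_A={p.k_A}, dt={dt}); "
            "the learning gains are too large for this sample interval")
    return state


@dataclass
class TrackedRecord:
    """Per-sample output of tracking a whole signal: estimate, residual,
    instantaneous frequency and phase, aligned with the input."""

    fs_hz: float
    t0_s: float
    y: np.ndarray
    y_hat: np.ndarray
    e: np.ndarray
    omega: np.ndarray
    phi: np.ndarray

    def time(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.y)) / self.fs_hz

    def error_series(self, channel: str = "error") -> TimeSeries:
        return TimeSeries(self.e, self.fs_hz, t0_s=self.t0_s, channel=channel)

    def estimate_series(self, channel: str = "estimate") -> TimeSeries:
        return TimeSeries(self.y_hat, self.fs_hz, t0_s=self.t0_s, channel=channel)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.time(), "y": self.y,
                             "y_hat": self.y_hat, "e": self.e,
                             "omega": self.omega, "phi": self.phi})


def ao_track(signal: TimeSeries, params: AOParams) -> TrackedRecord:
    """Run the oscillator over a whole signal.

    Output arrays are aligned sample-for-sample with the input; entry ``t``
    holds the post-update state after consuming input sample ``t``.
    """
    n = signal.n
    dt = signal.dt_s
    state = ao_init(params)
    y = signal.values
    y_hat = np.empty(n)
    e = np.empty(n)
    omega = np.empty(n)
    phi = np.empty(n)
    # hoist backend constants out of the loop for speed
    p = params
    if p.backend == "fourier":
        orders = np.arange(1, p.n_harmonics + 1)
        for t in range(n):
            arg = orders * state.phi
            sin_b, cos_b = np.sin(arg), np.cos(arg)
            y_pre = state.alpha0 + float(state.alpha @ sin_b + state.beta @ cos_b)
            err = y[t] - y_pre
            coupling = p.k_P * err * math.cos(state.phi)
            state.phi = (state.phi + dt * (state.omega + coupling)) % _TWO_PI
            state.omega = min(max(state.omega + dt * coupling,
                                  p.omega_min_rad_s), p.omega_max_rad_s)
            gain = dt * p.k_A * err
            state.alpha0 += gain
            state.alpha += gain * sin_b
            state.beta += gain * cos_b
            arg = orders * state.phi
            yh = state.alpha0 + float(state.alpha @ np.sin(arg) + state.beta @ np.cos(arg))
            state.y_hat = yh
            state.e = y[t] - yh
            y_hat[t] = yh
            e[t] = state.e
            omega[t] = state.omega
            phi[t] = state.phi
    else:
        for t in range(n):
            ao_step(state, float(y[t]), dt)
            y_hat[t] = state.y_hat
            e[t] = state.e
            omega[t] = state.omega
            phi[t] = state.phi
    if n and not np.all(np.isfinite(y_hat)):
        bad = int(np.flatnonzero(~np.isfinite(y_hat))[0])
        raise AONumericalError(f"oscillator diverged at sample {bad}")
    return TrackedRecord(fs_hz=signal.fs_hz, t0_s=signal.t0_s, y=y.copy(),
                         y_hat=y_hat, e=e, omega=omega, phi=phi)


def tracking_metrics(measured: TimeSeries, estimated: TimeSeries,
                     window_s: float = 3.0) -> Tuple[float, float]:
    """Goodness-of-tracking over the trailing ``window_s`` of two series.

    Returns ``(rmsd, rho)``: root-mean-square difference (rad) and Pearson
    correlation.  If either series has zero variance over the window the
    correlation is undefined; ``rho`` is returned as NaN with a warning.
    """
    if measured.n != estimated.n:
        raise ValueError("series lengths differ")
    w = round(window_s * measured.fs_hz)
    if w < 2 or w > measured.n:
        raise ValueError(f"window of {w} samples invalid for series of length {measured.n}")
    m = measured.values[-w:]
    s = estimated.values[-w:]
    rmsd = float(np.sqrt(np.mean((m - s) ** 2)))
    if np.ptp(m) == 0.0 or np.ptp(s) == 0.0:
        warnings.warn("zero variance in tracking window; Pearson rho undefined")
        return rmsd, float("nan")
    rho = float(np.corrcoef(m, s)[0, 1])
    return rmsd, rho
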