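"""Synthetic gait generator.

Produces quasi-periodic lower-limb elevation-angle signals that emulate
steady treadmill walking, and tripping-perturbed trials in which the signal
abruptly departs from its rhythmic pattern.  The waveform model is a
truncated Fourier series on a stride phase that advances with
stride-to-stride period jitter; it is not a biomechanical model.  Presets
for a "shank"-like channel (spectral content concentrated in the first few
stride harmonics) and a "foot"-like channel (substantial power out to the
eighth harmonic) reproduce the qualitative spectral ordering seen in real
IMU elevation angles: distal segments carry more high-frequency content.

Reproducibility contract: identical configuration (including ``seed``)
yields bit-identical output, and a perturbed trial agrees sample-for-sample
with its unperturbed twin strictly before the perturbation onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "SyntheticGaitConfig",
    "PerturbationConfig",
    "Trial",
    "shank_config",
    "foot_config",
    "preset_config",
    "generate_steady",
    "stride_event_indices",
    "generate_trial",
    "generate_benchmark",
]

# (order, amplitude_rad, phase_rad) of each stride harmonic.
Harmonic = Tuple[int, float, float]

# Amplitudes are in the tenths-of-a-radian range typical of sagittal
# elevation angles at ~1 m/s; the foot swings through a wider arc than the
# shank.  The shank preset keeps >99% of its power in harmonics 1-3 (<4 Hz
# at a 0.8 Hz stride rate); the foot preset has a slowly decaying spectrum
# out to harmonic 8 (6.4 Hz), so its spectral centroid sits strictly
# higher and its waveform is harder to phase-lock.
_SHANK_HARMONICS: Tuple[Harmonic, ...] = (
    (1, 0.30, 0.0),
    (2, 0.06, 1.2),
    (3, 0.02, 2.4),
)
_FOOT_HARMONICS: Tuple[Harmonic, ...] = (
    (1, 0.60, 0.0),
    (2, 0.27, 0.9),
    (3, 0.18, 1.8),
    (4, 0.12, 2.7),
    (5, 0.08, 3.6),
    (6, 0.05, 4.5),
    (7, 0.03, 5.4),
    (8, 0.02, 0.3),
)


@dataclass(frozen=True)
class SyntheticGaitConfig:
    """Parameters of the steady-walking waveform model.

    Defaults correspond to steady treadmill walking at ~1 m/s: a stride
    period of 1.25 s with ~5% stride-to-stride variability, sampled at
    100 Hz, with 0.01 rad of additive measurement noise.
    """

    stride_period_s: float = 1.25
    fs_hz: float = 100.0
    harmonics: Tuple[Harmonic, ...] = _SHANK_HARMONICS
    mean_angle_rad: float = 0.0
    noise_sd_rad: float = 0.01
    period_jitter_frac: float = 0.048
    period_jitter_ac: float = 0.5
    seed: int = 0
    channel: str = "shank"

    def __post_init__(self) -> None:
        vals = [self.stride_period_s, self.fs_hz, self.mean_angle_rad,
                self.noise_sd_rad, self.period_jitter_frac]
        for h in self.harmonics:
            vals.extend(h[1:])
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite value in SyntheticGaitConfig")
        if self.stride_period_s <= 0:
            raise ValueError("stride_period_s must be positive")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.noise_sd_rad < 0:
            raise ValueError("noise_sd_rad must be non-negative")
        if self.period_jitter_frac < 0:
            raise ValueError("period_jitter_frac must be non-negative")
        if not (0 <= self.period_jitter_ac < 1):
            raise ValueError("period_jitter_ac must be in [0, 1)")
        orders = [h[0] for h in self.harmonics]
        if any(o < 1 or o != int(o) for o in orders):
            raise ValueError("harmonic orders must be integers >= 1")
        if len(set(orders)) != len(orders):
            raise ValueError("harmonic orders must be distinct")
        # normalise to a hashable tuple-of-tuples
        object.__setattr__(self, "harmonics",
                           tuple((int(o), float(a), float(p)) for o, a, p in self.harmonics))


def shank_config(**overrides) -> SyntheticGaitConfig:
    """Shank-like channel: low harmonic content (orders 1-3 dominant)."""
    return SyntheticGaitConfig(harmonics=_SHANK_HARMONICS, channel="shank", **overrides)


def foot_config(**overrides) -> SyntheticGaitConfig:
    """Foot-like channel: slowly decaying spectrum out to the eighth harmonic."""
    return SyntheticGaitConfig(harmonics=_FOOT_HARMONICS, channel="foot", **overrides)


_PRESETS = {"shank": shank_config, "foot": foot_config}


def preset_config(name: str, **overrides) -> SyntheticGaitConfig:
    """Look up a named channel preset (``"shank"`` or ``"foot"``)."""
    try:
        return _PRESETS[name](**overrides)
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


@dataclass(frozen=True)
class PerturbationConfig:
    """Description of an abrupt tripping-like disturbance.

    ``arrest`` (the default) holds the angle at its onset value for
    ``hold_duration_s`` — the hold-type deviation produced by braking the
    swing foot — then re-entrains exponentially to the steady pattern with
    time constant ``recovery_tau_s``.  ``offset`` adds a constant
    ``magnitude_rad`` from onset onward; ``ramp`` drifts linearly to
    ``magnitude_rad`` over the hold and stays there.
    """

    onset_s: float = 15.0
    hold_duration_s: float = 0.9
    mode: str = "arrest"
    magnitude_rad: float = 0.0
    recovery_tau_s: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("arrest", "offset", "ramp"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if self.onset_s < 0 or self.hold_duration_s < 0:
            raise ValueError("onset_s and hold_duration_s must be non-negative")
        if self.recovery_tau_s <= 0:
            raise ValueError("recovery_tau_s must be positive")


@dataclass
class Trial:
    """One trial: a signal plus ground-truth perturbation metadata."""

    signal: TimeSeries
    onset_index: Optional[int]
    channel: str
    perturbed: bool
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.perturbed != (self.onset_index is not None):
            raise ValueError("onset_index must be present iff perturbed")
        if self.onset_index is not None and not (0 <= self.onset_index < self.signal.n):
            raise ValueError("onset_index out of range")

    @property
    def onset_s(self) -> Optional[float]:
        if self.onset_index is None:
            return None
        return self.signal.t0_s + self.onset_index / self.signal.fs_hz


def _stride_boundaries(rng: np.random.Generator, cfg: SyntheticGaitConfig,
                       duration_s: float) -> np.ndarray:
    """Cumulative stride-start times covering [0, duration_s].

    Stride-period fluctuations follow a stationary AR(1) process,
    ``z_i = ac*z_{i-1} + sqrt(1-ac^2)*eps_i``, so the stride time drifts
    slowly (paced treadmill walking shows strongly autocorrelated timing)
    while keeping a stationary standard deviation of ``period_jitter_frac``
    of the mean period.  Innovations are clipped to +/-3 sd so a period can
    never collapse or go negative.
    """
    T = cfg.stride_period_s
    ac = cfg.period_jitter_ac
    innov_sd = math.sqrt(1.0 - ac * ac)
    bounds = [0.0]
    z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
    while bounds[-1] < duration_s + T:
        Ti = max(T * (1.0 + cfg.period_jitter_frac * z), 0.1 * T)
        bounds.append(bounds[-1] + Ti)
        z = ac * z + innov_sd * float(np.clip(rng.standard_normal(), -3.0, 3.0))
    return np.asarray(bounds)


def _steady_values(cfg: SyntheticGaitConfig, duration_s: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (values, stride_boundaries_s); consumes rng deterministically."""
    n = round(duration_s * cfg.fs_hz)
    bounds = _stride_boundaries(rng, cfg, duration_s)
    periods = np.diff(bounds)
    t = np.arange(n) / cfg.fs_hz
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(periods) - 1)
    # stride phase in cycles: integer part = stride count, fractional part =
    # normalised position within the current (jittered) stride
    phase = idx + (t - bounds[idx]) / periods[idx]
    y = np.full(n, cfg.mean_angle_rad, dtype=float)
    for order, amp, ph in cfg.harmonics:
        y += amp * np.sin(2.0 * np.pi * order * phase + ph)
    if cfg.noise_sd_rad > 0:
        y += cfg.noise_sd_rad * rng.standard_normal(n)
    return y, bounds


def generate_steady(cfg: SyntheticGaitConfig, duration_s: float) -> TimeSeries:
    """Generate a steady quasi-periodic elevation-angle signal.

    The signal is ``mean + sum_i amp_i*sin(2*pi*order_i*phase(t) + phase_i)``
    where ``phase(t)`` advances by one cycle per (jittered) stride, plus
    additive white Gaussian noise.  Deterministic for a fixed config.
    """
    if duration_s < 2 * cfg.stride_period_s:
        raise ValueError("duration_s must cover at least two strides")
    rng = np.random.default_rng(cfg.seed)
    y, _ = _steady_values(cfg, duration_s, rng)
    return TimeSeries(y, cfg.fs_hz, t0_s=0.0, channel=cfg.channel)


def stride_event_indices(cfg: SyntheticGaitConfig, duration_s: float) -> np.ndarray:
    """Ground-truth stride-start sample indices for a steady signal.

    These are the generator's own stride boundaries (the synthetic analogue
    of heel-strike events); they replicate exactly the boundaries used by
    :func:`generate_steady` for the same config and duration.
    """
    rng = np.random.default_rng(cfg.seed)
    bounds = _stride_boundaries(rng, cfg, duration_s)
    n = round(duration_s * cfg.fs_hz)
    idx = np.round(bounds * cfg.fs_hz).astype(int)
    return idx[(idx >= 0) & (idx < n)]


def generate_trial(gait_cfg: SyntheticGaitConfig,
                   pert_cfg: Optional[PerturbationConfig] = None,
                   duration_s: float = 18.0,
                   trial_id: str = "") -> Trial:
    """Generate one 18-s trial, optionally with a tripping-like perturbation.

    The perturbation is applied on top of the steady signal, so a perturbed
    trial and its unperturbed twin (same config) are identical strictly
    before the onset sample.
    """
    steady = generate_steady(gait_cfg, duration_s)
    if pert_cfg is None:
        return Trial(steady, None, gait_cfg.channel, False, trial_id=trial_id)

    fs = gait_cfg.fs_hz
    n = steady.n
    i0 = round(pert_cfg.onset_s * fs)
    if not (0 <= i0 < n):
        raise ValueError(f"perturbation onset {pert_cfg.onset_s} s outside trial of {duration_s} s")
    if pert_cfg.onset_s + pert_cfg.hold_duration_s >= duration_s:
        raise ValueError("onset_s + hold_duration_s must fall inside the trial")

    y = steady.values.copy()
    i1 = min(round((pert_cfg.onset_s + pert_cfg.hold_duration_s) * fs), n)
    if pert_cfg.mode == "arrest":
        held = y[i0]
        y[i0:i1] = held
        if i1 < n:
            k = np.arange(n - i1) / fs
            y[i1:] = steady.values[i1:] + (held - steady.values[i1]) * np.exp(-k / pert_cfg.recovery_tau_s)
    elif pert_cfg.mode == "offset":
        y[i0:] += pert_cfg.magnitude_rad
    else:  # ramp
        m = i1 - i0
        if m > 0:
            y[i0:i1] += pert_cfg.magnitude_rad * np.arange(m) / m
        y[i1:] += pert_cfg.magnitude_rad
    sig = TimeSeries(y, fs, t0_s=0.0, channel=gait_cfg.channel)
    return Trial(sig, i0, gait_cfg.channel, True, trial_id=trial_id)


def _subseed(master_seed: int, index: int) -> int:
    """Counter-based per-trial seed: stable under growth of the trial set."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


def generate_benchmark(n_perturbed: int, n_unperturbed: int,
                       gait_cfg: SyntheticGaitConfig,
                       pert_cfg: Optional[PerturbationConfig] = None,
                       seed: int = 0,
                       duration_s: float = 18.0) -> list[Trial]:
    """Generate a reproducible benchmark set of trials.

    Trials ``0 .. n_perturbed-1`` are perturbed (using ``pert_cfg`` or the
    default arrest perturbation), the rest are unperturbed.  Each trial's
    generator is seeded from ``(seed, trial_index)``, so enlarging the set
    never changes earlier trials.
    """
    if n_perturbed < 0 or n_unperturbed < 0:
        raise ValueError("trial counts must be non-negative")
    if n_perturbed > 0 and pert_cfg is None:
        pert_cfg = PerturbationConfig()
    trials = []
    for i in range(n_perturbed + n_unperturbed):
        cfg_i = replace(gait_cfg, seed=_subseed(seed, i))
        pert = pert_cfg if i < n_perturbed else None
        trials.append(generate_trial(cfg_i, pert, duration_s=duration_s,
                                     trial_id=f"trial{i:03d}"))
    return trials
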