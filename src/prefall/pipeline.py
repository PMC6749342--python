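"""End-to-end detection pipeline: oscillator -> detector -> classification.

Covers trial-level detection and TP/FP/FN/TN classification, aggregation
into mean detection time (MDT) and false-alarm percentage, the two-stage
calibration procedure (oscillator gains first, detector parameters second)
over factorial grids, and stride segmentation utilities.

Classification rules (per trial):

* perturbed trial, detection strictly before onset          -> FP
* perturbed trial, detection within (onset, onset + 1 s]    -> TP
* perturbed trial, otherwise (late or no detection)         -> FN
* unperturbed trial, any detection                          -> FP
* unperturbed trial, no detection                           -> TN

MDT is the mean (and across-trial SD) of detection times over TP trials
only.  The false-alarm percentage is 100*(FP+FN)/n_trials; class counts are
reported alongside so any alternative denominator can be recomputed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detector import ATBAParams, DetectionTrace, run_detector
from .oscillator import AOParams, ao_track, tracking_metrics
from .synthetic import Trial
from .timeseries import TimeSeries

__all__ = [
    "TuningGrid",
    "DetectionResult",
    "EvalSummary",
    "StrideSet",
    "TrialTooShortError",
    "classify_detection",
    "detect_trial",
    "evaluate",
    "tune_ao",
    "tune_atba",
    "select_best",
    "segment_strides",
]

#: Detection window after perturbation onset within which a detection
#: counts as a true positive, seconds.
DETECTION_WINDOW_S = 1.0

#: Tracking-quality gates for oscillator calibration.
RMSD_GATE_RAD = 0.1
RHO_GATE = 0.9


class TrialTooShortError(ValueError):
    """Trial shorter than the detector warm-up: unevaluable, not an FN."""


@dataclass(frozen=True)
class TuningGrid:
    """Factorial calibration grids.

    Defaults: phase gain 1-100 (1 plus multiples of 10), amplitude gain
    1-50 likewise, window length {200, 300, 400} samples, shaping factor
    {3, 3.5, 4}, consecutive-warning count {6, 8, 10}.
    """

    kP_values: tuple = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    kA_values: tuple = (1, 10, 20, 30, 40, 50)
    w_values: tuple = (200, 300, 400)
    k_values: tuple = (3.0, 3.5, 4.0)
    r_values: tuple = (6, 8, 10)

    def __post_init__(self) -> None:
        for name in ("kP_values", "kA_values", "w_values", "k_values", "r_values"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, tuple(vals))


@dataclass
class DetectionResult:
    """Outcome of running the pipeline on one trial."""

    trial_id: str
    classification: str  # one of TP, FP, FN, TN
    detected_at_s: Optional[float] = None
    detection_time_s: Optional[float] = None  # detected_at - onset, perturbed trials


@dataclass
class EvalSummary:
    """Aggregate performance over a set of trials."""

    n_trials: int
    n_tp: int
    n_fp: int
    n_fn: int
    n_tn: int
    mdt_s: Optional[float]
    mdt_sd_s: Optional[float]
    fa_pct: float
    results: list = field(default_factory=list, repr=False)

    @classmethod
    def from_results(cls, results: Sequence[DetectionResult]) -> "EvalSummary":
        if not results:
            raise ValueError("no results to summarise")
        counts = {c: sum(r.classification == c for r in results)
                  for c in ("TP", "FP", "FN", "TN")}
        tp_times = [r.detection_time_s for r in results
                    if r.classification == "TP" and r.detection_time_s is not None]
        if tp_times:
            mdt = float(np.mean(tp_times))
            mdt_sd = float(np.std(tp_times, ddof=1)) if len(tp_times) > 1 else 0.0
        else:
            mdt = mdt_sd = None
        n = len(results)
        fa = 100.0 * (counts["FP"] + counts["FN"]) / n
        return cls(n_trials=n, n_tp=counts["TP"], n_fp=counts["FP"],
                   n_fn=counts["FN"], n_tn=counts["TN"],
                   mdt_s=mdt, mdt_sd_s=mdt_sd, fa_pct=fa, results=list(results))


def classify_detection(perturbed: bool, onset_s: Optional[float],
                       detected_at_s: Optional[float],
                       window_s: float = DETECTION_WINDOW_S) -> str:
    """Apply the TP/FP/FN/TN rules to a single detection outcome."""
    if not perturbed:
        return "FP" if detected_at_s is not None else "TN"
    if onset_s is None:
        raise ValueError("perturbed trial requires an onset time")
    if detected_at_s is None:
        return "FN"
    dt = detected_at_s - onset_s
    if dt < 0:
        return "FP"
    if 0 < dt <= window_s:
        return "TP"
    return "FN"


def _result_from_trace(trial: Trial, trace: DetectionTrace) -> DetectionResult:
    det_s = trace.detected_at_s
    onset_s = trial.onset_s
    cls = classify_detection(trial.perturbed, onset_s, det_s)
    dt = None
    if trial.perturbed and det_s is not None:
        dt = det_s - onset_s
    return DetectionResult(trial_id=trial.trial_id, classification=cls,
                           detected_at_s=det_s, detection_time_s=dt)


def detect_trial(trial: Trial, ao_params: AOParams,
                 atba_params: ATBAParams) -> DetectionResult:
    """Run oscillator tracking and threshold detection on one trial."""
    if trial.signal.n < atba_params.w + 1:
        raise TrialTooShortError(
            f"trial {trial.trial_id!r} has {trial.signal.n} samples; the detector "
            f"needs more than w={atba_params.w} to leave warm-up")
    rec = ao_track(trial.signal, ao_params)
    trace = run_detector(rec.error_series(), atba_params)
    return _result_from_trace(trial, trace)


def evaluate(trials: Sequence[Trial], ao_params: AOParams,
             atba_params: ATBAParams) -> EvalSummary:
    """Detect on every trial and aggregate MDT / false-alarm statistics."""
    if not trials:
        raise ValueError("empty trial list")
    results = [detect_trial(t, ao_params, atba_params) for t in trials]
    return EvalSummary.from_results(results)


def _pre_onset_slice(trial: Trial) -> TimeSeries:
    stop = trial.onset_index if trial.perturbed else trial.signal.n
    return trial.signal.slice_samples(0, stop)


def tune_ao(steady_trials: Sequence[Trial], grid: TuningGrid,
            ao_template: Optional[AOParams] = None,
            window_s: float = 3.0) -> pd.DataFrame:
    """Stage one of calibration: sweep the learning-gain grid.

    For each (k_P, k_A) pair, tracks the pre-onset portion of every trial,
    computes RMSD and Pearson rho over the trailing ``window_s``, and
    averages across trials.  A pair passes if mean RMSD < 0.1 rad and mean
    rho > 0.9.  Returns a tidy table (k_P, k_A, rmsd, rho, passed).
    """
    if not steady_trials:
        raise ValueError("empty trial list")
    template = ao_template or AOParams(k_P=0.0, k_A=0.0)
    slices = [_pre_onset_slice(t) for t in steady_trials]
    for s in slices:
        if s.duration_s < window_s:
            raise ValueError("trials must contain at least the evaluation window "
                             "of steady walking before onset")
    rows = []
    for kP, kA in itertools.product(grid.kP_values, grid.kA_values):
        params = AOParams(k_P=float(kP), k_A=float(kA),
                          n_harmonics=template.n_harmonics,
                          omega_init_rad_s=template.omega_init_rad_s,
                          omega_min_rad_s=template.omega_min_rad_s,
                          omega_max_rad_s=template.omega_max_rad_s,
                          backend=template.backend,
                          n_kernels=template.n_kernels)
        rmsds, rhos = [], []
        for s in slices:
            rec = ao_track(s, params)
            rmsd, rho = tracking_metrics(s, rec.estimate_series(), window_s)
            rmsds.append(rmsd)
            rhos.append(rho)
        mean_rmsd = float(np.mean(rmsds))
        mean_rho = float(np.mean(rhos))
        passed = bool(mean_rmsd < RMSD_GATE_RAD
                      and math.isfinite(mean_rho) and mean_rho > RHO_GATE)
        rows.append({"k_P": kP, "k_A": kA, "rmsd": mean_rmsd,
                     "rho": mean_rho, "passed": passed})
    return pd.DataFrame(rows)


def tune_atba(trials: Sequence[Trial], ao_params: AOParams,
              grid: TuningGrid) -> pd.DataFrame:
    """Stage two of calibration: factorial sweep of the detector grid.

    With the oscillator gains fixed, the residual stream of each trial is
    computed once and every (w, k, r) cell is evaluated on the cached
    residuals.  Returns one row per cell with the EvalSummary fields.
    """
    if not trials:
        raise ValueError("empty trial list")
    errors = [ao_track(t.signal, ao_params).error_series() for t in trials]
    rows = []
    for w, k, r in itertools.product(grid.w_values, grid.k_values, grid.r_values):
        params = ATBAParams(w=int(w), k=float(k), r=int(r))
        results = []
        for trial, err in zip(trials, errors):
            if err.n < params.w + 1:
                raise TrialTooShortError(
                    f"trial {trial.trial_id!r} shorter than window w={params.w}")
            trace = run_detector(err, params)
            results.append(_result_from_trace(trial, trace))
        summ = EvalSummary.from_results(results)
        rows.append({"w": int(w), "k": float(k), "r": int(r),
                     "mdt_s": summ.mdt_s, "mdt_sd_s": summ.mdt_sd_s,
                     "fa_pct": summ.fa_pct, "n_tp": summ.n_tp,
                     "n_fp": summ.n_fp, "n_fn": summ.n_fn, "n_tn": summ.n_tn})
    return pd.DataFrame(rows)


def select_best(table: pd.DataFrame,
                fa_threshold_pct: float = 10.0) -> Optional[pd.Series]:
    """Best detector cell: minimum MDT among cells with acceptable
    false-alarm rate (strictly below the threshold).  Returns None when no
    cell qualifies."""
    ok = table[(table["fa_pct"] < fa_threshold_pct) & table["mdt_s"].notna()]
    if ok.empty:
        return None
    return ok.loc[ok["mdt_s"].idxmin()]


@dataclass
class StrideSet:
    """Strides normalised to the gait cycle: each row is one stride
    resampled to 101 points (0..100% of the cycle)."""

    strides: np.ndarray  # (n_strides, 101)
    mean_cycle: np.ndarray
    sd_cycle: np.ndarray
    stride_durations_s: np.ndarray


def segment_strides(signal: TimeSeries, events: Sequence[int]) -> StrideSet:
    """Cut a signal at gait events and time-normalise each stride.

    ``events`` are strictly increasing sample indices (e.g. heel strikes);
    each inter-event segment, endpoints included, is linearly interpolated
    onto 101 equally spaced points of normalised time.
    """
    events = np.asarray(events, dtype=int)
    if events.size < 2:
        raise ValueError("need at least two events to form a stride")
    if np.any(np.diff(events) <= 0):
        raise ValueError("events must be strictly increasing")
    if events[0] < 0 or events[-1] >= signal.n:
        raise ValueError("events out of signal range")
    grid = np.linspace(0.0, 1.0, 101)
    strides = []
    durations = []
    for a, b in zip(events[:-1], events[1:]):
        seg = signal.values[a:b + 1]
        x = np.linspace(0.0, 1.0, len(seg))
        strides.append(np.interp(grid, x, seg))
        durations.append((b - a) / signal.fs_hz)
    strides = np.vstack(strides)
    return StrideSet(strides=strides,
                     mean_cycle=strides.mean(axis=0),
                     sd_cycle=strides.std(axis=0),
                     stride_durations_s=np.asarray(durations))
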