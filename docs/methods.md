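# Methods

## The detection problem

A trip arrests the swing foot while the body keeps moving forward; the
kinematic signature is an abrupt departure of the lower-limb elevation
angles from their steady quasi-periodic pattern, beginning at the
perturbation onset and evolving over the following compensatory stride
(~1 s).  The pipeline must flag this departure quickly (well inside the
1-s window in which a detection still leaves time for a protective
response) while almost never firing during steady walking.

## Adaptive-oscillator estimator

The estimator is an adaptive Fourier series on a learned phase.  State:
phase φ, fundamental frequency ω (rad/s), offset α₀ and per-harmonic
quadrature coefficients αᵢ, βᵢ (i = 1…N).  One forward-Euler step at the
signal's sample interval dt, with input sample y:

    ŷ  = α₀ + Σᵢ (αᵢ sin iφ + βᵢ cos iφ)
    e  = y − ŷ
    φ  ← φ + dt (ω + k_P · e · cos φ)        (wrapped to [0, 2π))
    ω  ← clamp(ω + dt · k_P · e · cos φ)
    α₀ ← α₀ + dt · k_A · e
    αᵢ ← αᵢ + dt · k_A · e · sin iφ
    βᵢ ← βᵢ + dt · k_A · e · cos iφ

The stored residual is recomputed against the post-update state, so it is
exactly the signal handed to the detector.

Design notes:

* **Quadrature pairs.**  Each harmonic carries both sin and cos
  coefficients.  A sine-only basis spans only waveforms odd-symmetric in
  φ; on generic gait waveforms it leaves an irreducible residual
  (~0.045 rad on the shank preset, measured with noise and jitter
  disabled) that would both fail the calibration gates and blind the
  detector.  With the quadrature pair the steady-state residual is set by
  noise and stride-timing variability (~0.015 rad), as it should be.
* **Fundamental-only phase coupling.**  The residual feeds φ and ω only
  through cos φ (not through the higher harmonics).  This is the simplest
  law satisfying the zero-lag contract; coupling through all harmonics is
  a possible variant not implemented.
* **Frequency clamp.**  ω is confined to [2π·0.3, 2π·2.5] rad/s
  (cadences from very slow walking to running).  During a long aperiodic
  transient — exactly the situation after a trip — the frequency update is
  driven by a non-rhythmic residual and can otherwise run away or
  collapse; the clamp keeps the oscillator recoverable.
* **Initialisation.**  φ=0, coefficients 0, ω = 2π/1.25 rad/s, the
  fundamental of a typical 1.25-s stride at ~1 m/s.
* **Integration.**  Forward Euler at dt = 0.01 s (100 Hz).  Halving dt
  moves the converged frequency by <1%, and the dt=0.01 trajectory agrees
  with a dt=10⁻⁴ reference integration to <1% (both asserted in tests);
  nothing finer is warranted.
* **Divergence guard.**  Gains too large for dt (e.g. k_P ~ 10⁶) drive
  the state non-finite; this raises a diagnostic error rather than
  propagating NaNs.
* **Kernel backend.**  A second waveform backend replaces the Fourier sum
  with a normalised von-Mises kernel expansion over phase (18 kernels by
  default), with the same phase/frequency law.  It realises the same
  contract and is exposed for comparison; the Fourier backend is the
  default and the one used everywhere else.  Kernel weights learn only
  when φ visits them, so they want a larger k_A (~n_kernels times).

Tunables: k_P ∈ [1, 100] and k_A ∈ [1, 50] (the calibration grids), with
N = 6 harmonics — enough to cover a foot-like channel's spectrum at a
0.8 Hz fundamental up to ~5 Hz.

## Threshold detector

Over the *w* residual samples strictly before the current frame (the
tested sample never enters its own statistics), compute mean μ and
population standard deviation σ; warn when |e − μ| > k·max(σ, σ_floor);
detect on the r-th consecutive warning.  Details:

* Statistics are on **signed** residuals and the band is two-sided
  (μ ± kσ).  For well-tracked residuals μ ≈ 0, where this coincides with
  comparing |e| against μ + kσ.
* The window keeps advancing during a warning streak (no freezing).  With
  a saturating step this still yields detection exactly r samples into the
  step for every grid cell (w ≥ 200, k ≤ 4, r ≤ 10): after j < r step
  samples have entered the window, the band grows like k·S·√(j/w), which
  stays below the step's distance to μ.
* The first w frames are warm-up: no warning can be emitted, so w is also
  the minimum session length before the detector is armed (4 s at the
  default w = 400).
* σ_floor = 10⁻⁶ rad guards the degenerate constant-input case where
  σ = 0 would make any fluctuation an instant warning.
* Detection fires once per stream; the trace keeps recording warnings and
  the (r-capped) streak afterwards for diagnostics.
* A single non-warning sample resets the streak (strict reading of
  "consecutive").
* The streaming implementation (`atba_step`) uses running first/second
  moments; the batch path (`run_detector`) uses cumulative sums and
  run-length arithmetic.  Both match a from-scratch recomputation of every
  window to 10⁻¹⁰ (asserted in tests).

Defaults w = 400 samples, k = 3.5, r = 6 are the best cell of the
factorial calibration (below).  The shaping factor is motivated by the
Gaussian tail bound: a Gaussian residual leaves μ ± 3σ with probability
<1%, and k = 3.5 cuts the per-sample false-warning rate to ~4.7·10⁻⁴,
which the r-consecutive rule then suppresses essentially to zero.

## Trial evaluation and calibration

Per trial: FP if a detection precedes the perturbation onset (or occurs at
all on an unperturbed trial); TP if it lands in (onset, onset + 1 s]; FN
otherwise (including a detection later than 1 s, and the measure-zero case
of a detection exactly at the onset sample); TN for a clean unperturbed
trial.  Aggregates: MDT = mean ± across-trial SD of TP detection times;
FA% = 100·(FP+FN)/n_trials.  Class counts are always reported so
alternative denominators (e.g. FA over perturbed trials only) can be
recomputed.  Trials shorter than the warm-up raise an "unevaluable" error
instead of counting as FN.

Calibration is two-stage, mirroring how the detector would be deployed:

1. `tune_ao` sweeps (k_P, k_A) over {1, 10, …, 100} × {1, 10, …, 50},
   tracks the pre-onset portion of each trial and averages RMSD and
   Pearson ρ over the trailing 3 s; a pair passes if RMSD < 0.1 rad and
   ρ > 0.9.
2. `tune_atba` fixes the gains, caches each trial's residual stream, and
   evaluates every (w, k, r) ∈ {200, 300, 400} × {3, 3.5, 4} × {6, 8, 10}
   cell; the best cell is the minimum-MDT cell among those with FA below
   10%.

## Synthetic gait generator

The generator emulates the statistical structure the detector cares
about, not biomechanics.  A steady signal is

    θ(t) = mean + Σₒ aₒ sin(2π·o·Φ(t) + ψₒ) + ε(t),   ε ~ N(0, σ_n²)

where Φ(t) advances by one cycle per stride and each stride's period is
T·(1 + 0.048·z), with z a stationary AR(1) sequence (lag-1
autocorrelation 0.5, innovations clipped at ±3 SD).  Defaults: T = 1.25 s
(so the period SD is 0.06 s, matching steady treadmill walking at
~1 m/s), fs = 100 Hz, σ_n = 0.01 rad (an IMU-grade noise floor well below
the 0.1-rad calibration gate).  The AR(1) choice reflects that paced
treadmill walking drifts in cadence slowly rather than jumping
stride-to-stride; with white per-stride jitter the phase is so
unpredictable that even the best gains leave a residual floor that buries
the perturbation response.

Channel presets (amplitudes in rad):

* **shank** — harmonics 1–3, amplitudes (0.30, 0.06, 0.02): >99% of power
  below 4 Hz.
* **foot** — harmonics 1–8, amplitudes (0.60, 0.27, 0.18, 0.12, 0.08,
  0.05, 0.03, 0.02): a wider arc with a slowly decaying spectrum past the
  estimator's 6-harmonic representation, so its spectral centroid is
  strictly above the shank's and its waveform is intrinsically harder to
  phase-lock.  The presets were calibrated once against the qualitative
  published structure (spectral ordering between channels; a smaller
  passing gain region for the foot; an FN-dominant foot failure mode
  under arrest perturbations) and then frozen.

Perturbations start at 15 s of an 18-s trial.  The default **arrest** mode
holds the angle at its onset value for 0.9 s — the hold-type deviation a
rope-braked swing foot produces — then re-entrains exponentially to the
steady pattern (τ = 0.3 s, i.e. recovery within the ~1.1-s compensatory
stride).  **offset** and **ramp** modes add a constant or linearly growing
bias for testing other deviation shapes.  Perturbed and unperturbed twins
from the same seed are identical strictly before onset, and benchmark
trial i is seeded from (master_seed, i), so enlarging a benchmark never
changes existing trials.

What the generator does **not** emulate: multi-channel coupling between
segments, waveform shape changes with speed, reactive balance kinematics
after the arrest (real recovery is not an exponential return to the old
pattern), soft-tissue/sensor artefacts, or non-stationary cadence beyond
AR(1) drift.  Consequently, passing benchmarks here demonstrates the
pipeline's mechanics — tracking, thresholding, latency, tuning structure —
not field performance on human falls; published human-subject figures
(MDT ≈ 0.37 ± 0.11 s with FA ≈ 9.4% on the shank) come from recordings
that are not public, and the synthetic analogue is deliberately only held
to the qualitative bands (FA < 10%, MDT < 1 s, foot worse than shank).

## Problem sizes used in tests

The acceptance-style benchmark uses 40 perturbed + 80 unperturbed 18-s
trials per channel (the study's per-subject 5+10 protocol scaled up for
stable rates); the tuning-region comparisons use reduced grids spanning
the corners of the full factorial; the noise-floor test runs 10⁴
independent 15-s Gaussian residual streams and requires zero detections.
The full suite runs in well under a minute on one CPU.

## Known limitations

* The frequency clamp, not an explicit re-entrainment controller, is what
  keeps the oscillator recoverable after long aperiodic transients.
* `tune_ao`'s pass region on synthetic data is broader for small k_A than
  the published human-data region; the gate separates channels and gain
  regimes qualitatively, not cell-for-cell.
* The CSV reader trusts the JSON sidecar for metadata; without it a trial
  is assumed unperturbed (with a logged warning).
* Detection timestamps are reported at the sample where the streak
  reaches r; subtracting (r−1)/fs would give the first warning of the
  detecting streak if a different convention is needed.
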