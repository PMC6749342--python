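"""Adaptive oscillator: update-law identities, convergence, tracking
quality, and the frozen-learner / step-size invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prefall import (
    AOParams,
    PerturbationConfig,
    TimeSeries,
    ao_init,
    ao_step,
    ao_track,
    generate_steady,
    generate_trial,
    shank_config,
    tracking_metrics,
)


def sine_series(freq_hz, amp=0.3, fs=100.0, duration_s=15.0, phase=0.0):
    t = np.arange(round(duration_s * fs)) / fs
    return TimeSeries(amp * np.sin(2 * np.pi * freq_hz * t + phase), fs)


class TestInit:
    def test_fresh_state_is_zero(self):
        s = ao_init(AOParams(k_P=20, k_A=1))
        assert s.y_hat == 0.0 and s.alpha0 == 0.0
        assert not s.alpha.any() and not s.beta.any()

    def test_omega_init_outside_clamp_rejected(self):
        with pytest.raises(ValueError):
            ao_init(AOParams(k_P=1, k_A=1, omega_init_rad_s=100.0))

    def test_equal_params_equal_states(self):
        a = ao_init(AOParams(k_P=5, k_A=2))
        b = ao_init(AOParams(k_P=5, k_A=2))
        assert a.phi == b.phi and a.omega == b.omega
        np.testing.assert_array_equal(a.alpha, b.alpha)

    @pytest.mark.parametrize("kwargs", [
        {"k_P": -1.0, "k_A": 1.0},
        {"k_P": 1.0, "k_A": float("nan")},
        {"k_P": 1.0, "k_A": 1.0, "n_harmonics": 0},
        {"k_P": 1.0, "k_A": 1.0, "omega_min_rad_s": 5.0, "omega_max_rad_s": 2.0},
        {"k_P": 1.0, "k_A": 1.0, "backend": "wavelet"},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AOParams(**kwargs)


class TestZeroGainInvariance:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1.0, 1.0), min_size=1, max_size=50))
    def test_frozen_learner_never_changes_coefficients(self, samples):
        params = AOParams(k_P=0.0, k_A=0.0)
        state = ao_init(params)
        omega0 = state.omega
        for y in samples:
            state = ao_step(state, y, 0.01)
            assert state.omega == omega0
            assert state.alpha0 == 0.0
            assert not state.alpha.any() and not state.beta.any()
        # prediction is identically zero, so the residual is the input
        assert state.e == samples[-1]


class TestConvergence:
    def test_sinusoid_frequency_and_error(self):
        """0.8 Hz sinusoid, k_P=20, k_A=1: frequency recovered to <5% and
        residual RMS over the last 3 s below 0.02 rad."""
        sig = sine_series(0.8)
        rec = ao_track(sig, AOParams(k_P=20, k_A=1))
        assert rec.omega[-1] == pytest.approx(2 * np.pi * 0.8, rel=0.05)
        assert np.sqrt(np.mean(rec.e[-300:] ** 2)) < 0.02

    def test_matches_fine_step_reference_integration(self):
        """The dt=0.01 Euler path agrees with an independent reference
        integration of the same ODEs at dt=1e-4."""
        freq, amp, kP, kA = 0.8, 0.3, 20.0, 1.0
        # reference: single-harmonic state, plain-float loop
        dt = 1e-4
        n = round(15.0 / dt)
        phi, om = 0.0, 2 * np.pi / 1.25
        a0 = a1 = b1 = 0.0
        for i in range(n):
            y = amp * math.sin(2 * np.pi * freq * i * dt)
            s, c = math.sin(phi), math.cos(phi)
            e = y - (a0 + a1 * s + b1 * c)
            coup = kP * e * c
            phi += dt * (om + coup)
            om += dt * coup
            a0 += dt * kA * e
            a1 += dt * kA * e * s
            b1 += dt * kA * e * c
        rec = ao_track(sine_series(freq), AOParams(k_P=kP, k_A=kA, n_harmonics=1))
        assert rec.omega[-1] == pytest.approx(om, rel=0.01)

    @pytest.mark.parametrize("freq", [0.5, 0.75, 1.0, 1.25, 1.5])
    def test_frequency_recovery_across_band(self, freq):
        rec = ao_track(sine_series(freq, duration_s=20.0), AOParams(k_P=20, k_A=1))
        assert rec.omega[-1] == pytest.approx(2 * np.pi * freq, rel=0.05)

    def test_halving_dt_barely_moves_final_omega(self):
        finals = []
        for fs in (100.0, 200.0):
            rec = ao_track(sine_series(0.8, fs=fs), AOParams(k_P=20, k_A=1))
            finals.append(rec.omega[-1])
        assert abs(finals[1] - finals[0]) / finals[0] < 0.01

    def test_constant_input_offset_learning(self):
        """On a constant input the offset coefficient converges to the
        constant and the residual envelope decays."""
        n = 1500
        sig = TimeSeries(np.full(n, 0.25), 100.0)
        rec = ao_track(sig, AOParams(k_P=0.0, k_A=2.0))
        assert abs(rec.y_hat[-1] - 0.25) < 0.01
        env_early = np.max(np.abs(rec.e[:100]))
        env_late = np.max(np.abs(rec.e[-100:]))
        assert env_late < 0.1 * env_early

    def test_steady_rmsd_nondecreasing_in_frequency(self):
        """Zero-lag low-pass behavior: with fixed gains, steady tracking of
        a jittered single-harmonic gait degrades as the fundamental
        frequency rises."""
        rmsds = []
        from prefall import SyntheticGaitConfig

        for T in (2.0, 1.25, 0.9, 0.7):  # 0.5 to 1.43 Hz
            cfg = SyntheticGaitConfig(seed=4, stride_period_s=T,
                                      harmonics=((1, 0.3, 0.0),))
            rec = ao_track(generate_steady(cfg, 18.0), AOParams(k_P=20, k_A=1))
            rmsds.append(float(np.sqrt(np.mean(rec.e[-500:] ** 2))))
        # monotone trend with 10% slack per step against seed noise
        for lo, hi in zip(rmsds[:-1], rmsds[1:]):
            assert hi > 0.9 * lo
        assert rmsds[-1] > rmsds[0]


class TestKernelBackend:
    def test_kernel_tracks_offset_sinusoid(self):
        """The von-Mises kernel waveform learns non-odd waveforms too;
        kernel weights need a larger k_A since each kernel is updated only
        near its own phase."""
        sig = sine_series(0.8, phase=1.0, duration_s=20.0)
        sig = TimeSeries(sig.values + 0.1, sig.fs_hz)
        rec = ao_track(sig, AOParams(k_P=20, k_A=20, backend="kernel"))
        assert np.sqrt(np.mean(rec.e[-300:] ** 2)) < 0.05
        assert rec.omega[-1] == pytest.approx(2 * np.pi * 0.8, rel=0.05)

    def test_kernel_zero_gain_frozen(self):
        state = ao_init(AOParams(k_P=0, k_A=0, backend="kernel"))
        for y in (0.3, -0.2, 0.5):
            state = ao_step(state, y, 0.01)
        assert not state.alpha.any()


class TestTrackingOnGait:
    def test_shank_preset_passes_tuning_gates(self, shank_trial, shank_gains):
        pre = shank_trial.signal.slice_samples(0, shank_trial.onset_index)
        rec = ao_track(pre, shank_gains)
        rmsd, rho = tracking_metrics(pre, rec.estimate_series(), 3.0)
        assert rmsd < 0.1
        assert rho > 0.9

    def test_error_jumps_after_arrest(self, shank_gains):
        """Post-onset residual (0.5 s) exceeds 3x the pre-onset residual
        (3 s) on a well-tracked perturbed trial."""
        ratios = []
        for seed in (0, 1, 2, 3):
            tr = generate_trial(shank_config(seed=seed), PerturbationConfig())
            rec = ao_track(tr.signal, shank_gains)
            i0 = tr.onset_index
            pre = np.mean(np.abs(rec.e[i0 - 300:i0]))
            post = np.mean(np.abs(rec.e[i0:i0 + 50]))
            ratios.append(post / pre)
        assert np.mean(ratios) > 3.0

    def test_empty_signal_gives_empty_outputs(self, shank_gains):
        rec = ao_track(TimeSeries(np.empty(0), 100.0), shank_gains)
        assert len(rec.e) == 0 and len(rec.y_hat) == 0

    def test_track_alignment(self, shank_trial, shank_gains):
        rec = ao_track(shank_trial.signal, shank_gains)
        assert len(rec.e) == shank_trial.signal.n
        np.testing.assert_array_equal(rec.y, shank_trial.signal.values)
        assert np.allclose(rec.e, rec.y - rec.y_hat)


class TestTrackingMetrics:
    def test_identity(self):
        sig = sine_series(0.8, duration_s=5.0)
        rmsd, rho = tracking_metrics(sig, sig, 3.0)
        assert rmsd == 0.0
        assert rho == pytest.approx(1.0)

    def test_constant_offset(self):
        sig = sine_series(0.8, duration_s=5.0)
        off = TimeSeries(sig.values + 0.05, sig.fs_hz)
        rmsd, rho = tracking_metrics(sig, off, 3.0)
        assert rmsd == pytest.approx(0.05)
        assert rho == pytest.approx(1.0)

    def test_sign_flip(self):
        sig = sine_series(0.8, duration_s=5.0)
        neg = TimeSeries(-sig.values, sig.fs_hz)
        _, rho = tracking_metrics(sig, neg, 3.0)
        assert rho == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        const = TimeSeries(np.full(500, 0.1), 100.0)
        sig = sine_series(0.8, duration_s=5.0)
        with pytest.warns(UserWarning, match="zero variance"):
            _, rho = tracking_metrics(sig, const, 3.0)
        assert math.isnan(rho)


class TestNumericalSafety:
    def test_divergence_raises_with_diagnostic(self):
        sig = sine_series(0.8, duration_s=5.0)
        with pytest.raises(RuntimeError, match="gain|diverged"):
            ao_track(sig, AOParams(k_P=1e6, k_A=1e6))

    def test_omega_stays_clamped(self, shank_trial):
        rec = ao_track(shank_trial.signal, AOParams(k_P=100, k_A=1))
        p = AOParams(k_P=100, k_A=1)
        assert np.all(rec.omega >= p.omega_min_rad_s - 1e-12)
        assert np.all(rec.omega <= p.omega_max_rad_s + 1e-12)
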