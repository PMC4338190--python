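"""Marker extraction: recovery fits, variance, autocorrelation, windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import critslow as cs
from critslow.errors import (
    DegenerateFitError,
    EmptySeriesError,
    InsufficientBaselineError,
    InsufficientDataError,
    UndefinedACFError,
)
from critslow.markers import locate_perturbations


class TestFitRecovery:
    @pytest.mark.parametrize("lam", [2.0, 5.0, 20.0, 80.0, 200.0])
    def test_exact_recovery_over_two_decades(self, lam):
        t = np.arange(200) / 1000.0
        fit = cs.fit_recovery(3.0 * np.exp(-lam * t) + 1.0, 1000.0)
        assert fit.converged
        assert fit.lam == pytest.approx(lam, rel=1e-6)
        assert fit.a == pytest.approx(3.0, rel=1e-5)

    def test_reference_example(self):
        t = np.arange(200) / 1000.0
        fit = cs.fit_recovery(3.0 * np.exp(-2.0 * t) + 1.0, 1000.0)
        assert fit.lam == pytest.approx(2.0, abs=1e-6)

    def test_frozen_saddle_node_pulse_matches_linearization(self):
        cfg = cs.SDEConfig.saddle_node(
            sigma1=0.0, epsilon=0.0, y0=1.0, state0=(-math.sqrt(10.0),),
            pulse_amplitude=0.01, t_end=120.0,
        )
        det = cs.detrend_saddle_node(cs.simulate_saddle_node(cfg))
        i0 = int(round(60.0 / cfg.dt)) + 1
        fit = cs.fit_recovery(det.state[i0:i0 + 5000], 1.0 / cfg.dt)
        assert fit.lam == pytest.approx(2.0 * math.sqrt(0.1), rel=0.02)

    def test_white_noise_has_no_decay(self):
        rng = np.random.default_rng(0)
        fit = cs.fit_recovery(rng.standard_normal(2000), 1000.0)
        assert (not fit.converged) or fit.r_squared < 0.1

    def test_constant_segment(self):
        with pytest.raises(DegenerateFitError):
            cs.fit_recovery(np.ones(100), 1000.0)

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            cs.fit_recovery(np.arange(10.0), 1000.0)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0])
    def test_tracks_rate_on_noisy_decays(self, lam):
        # validity regime lambda * window >= 1
        rng = np.random.default_rng(42)
        t = np.arange(4000) / 1000.0
        lams = []
        for _ in range(10):
            seg = 0.2 * np.exp(-lam * t) + rng.normal(0, 0.002, len(t))
            lams.append(cs.fit_recovery(seg, 1000.0).lam)
        assert np.median(lams) == pytest.approx(lam, rel=0.10)


class TestSegmentVariance:
    def test_constant_is_zero(self):
        assert cs.segment_variance(np.full(100, 3.3)) == 0.0

    def test_population_convention(self):
        # +-1 alternating: population variance exactly 1
        seg = np.tile([1.0, -1.0], 50)
        assert cs.segment_variance(seg) == pytest.approx(1.0)

    @given(shift=st.floats(-1e3, 1e3), scale=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariant_scale_quadratic(self, shift, scale):
        seg = np.random.default_rng(5).standard_normal(256)
        base = cs.segment_variance(seg)
        assert cs.segment_variance(seg + shift) == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert cs.segment_variance(seg * scale) == pytest.approx(base * scale ** 2, rel=1e-9)

    def test_frozen_ou_matches_closed_form(self):
        # OU at rate lam: stationary variance sigma^2 / (2 lam), >= 20 seeds
        lam, sigma, dt, n = 1.0, 0.01, 0.01, 60000
        est = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = rng.standard_normal(n) * sigma * math.sqrt(dt)
            x = np.empty(n)
            x[0] = 0.0
            for i in range(1, n):
                x[i] = x[i - 1] * (1 - lam * dt) + w[i]
            est.append(cs.segment_variance(x[n // 10:]))
        assert np.mean(est) == pytest.approx(sigma ** 2 / (2 * lam), rel=0.10)


class TestAutocorrelation:
    def test_lag_one_is_unity(self):
        seg = np.random.default_rng(1).standard_normal(1000)
        assert cs.autocorrelation(seg, 1) == 1.0

    def test_ar1_matches_theory(self):
        rng = np.random.default_rng(2)
        n, phi = 50_000, 0.9
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        # lag-1-normalized ACF of AR(1): phi^(s-1)
        assert cs.autocorrelation(x, 10) == pytest.approx(phi ** 9, rel=0.05)

    def test_matches_statsmodels_ratio(self):
        sm = pytest.importorskip("statsmodels.tsa.stattools")
        seg = np.random.default_rng(3).standard_normal(4096).cumsum()
        acf = sm.acf(seg, nlags=50, adjusted=False, fft=False)
        for lag in (5, 20, 50):
            assert cs.autocorrelation(seg, lag) == pytest.approx(acf[lag] / acf[1], rel=1e-9)

    def test_constant_segment(self):
        with pytest.raises(UndefinedACFError):
            cs.autocorrelation(np.ones(100), 5)

    @pytest.mark.parametrize("lag", [0, 600])
    def test_lag_bounds(self, lag):
        with pytest.raises(InsufficientDataError):
            cs.autocorrelation(np.random.default_rng(0).standard_normal(1000), lag)

    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, shift, scale):
        seg = np.random.default_rng(6).standard_normal(512).cumsum()
        base = cs.autocorrelation(seg, 7)
        assert cs.autocorrelation(seg * scale + shift, 7) == pytest.approx(base, rel=1e-9)


class TestOnsetAndCriticalCurrent:
    def test_subthreshold_trace_has_no_onset(self):
        v = np.full(5000, -60.0)
        v[2000] = -40.0
        assert cs.detect_onset((v, 25000.0), 0.0) is None

    def test_inserted_spike_located_exactly(self):
        v = np.full(20000, -60.0)
        v[10000:10005] = 30.0
        assert cs.detect_onset((v, 25000.0), 0.0) == pytest.approx(10000 / 25000.0)

    def test_critical_current_constant(self, recording):
        import dataclasses

        rec = dataclasses.replace(recording, current_pA=np.full(10000, 100.0))
        assert cs.critical_current(rec, 3.0) == pytest.approx(100.0)

    def test_critical_current_staircase_weighted_mean(self, recording):
        # window straddling a step boundary: duration-weighted brute-force mean
        onset = recording.onset_time_s
        i_hz = recording.i_sampling_hz
        j0, j1 = int(round((onset - 1) * i_hz)), int(round(onset * i_hz))
        brute = float(np.mean(recording.current_pA[j0:j1]))
        assert cs.critical_current(recording, onset) == pytest.approx(brute, rel=1e-12)

    def test_early_onset_rejected(self, recording):
        with pytest.raises(InsufficientBaselineError):
            cs.critical_current(recording, 0.5)


class TestLocatePerturbations:
    def test_model_path_one_event_per_interval(self, sn_trajectory):
        det = cs.detrend_saddle_node(sn_trajectory)
        events = locate_perturbations(det)
        # pulses every 60 time units before t_c = 1600 -> 26 usable events
        assert len(events) == 26
        assert np.allclose(np.diff([e.pulse_time for e in events]), 60.0, atol=det.dt)

    def test_recording_schedule(self, recording):
        events = locate_perturbations(recording)
        onset = recording.onset_time_s
        sr = recording.v_sampling_hz
        for ev in events:
            assert ev.pre_stop - ev.pre_start == int(round(sr))
            assert ev.post_stop - ev.post_start == int(round(0.192 * sr))
            assert ev.post_stop / sr <= onset
        assert all(e.pulse_time < onset - 0.197 for e in events)

    def test_windows_never_overlap(self, recording):
        events = locate_perturbations(recording)
        spans = sorted(
            [(e.pre_start, e.pre_stop) for e in events]
            + [(e.post_start, e.post_stop) for e in events]
        )
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0

    def test_event_near_onset_dropped(self, recording):
        import dataclasses

        # move the onset to 40 ms after a pulse: that event's fit window crosses it
        target = recording.pulse_times_s[5]
        rec = dataclasses.replace(recording, onset_time_s=float(target) + 0.040)
        events = locate_perturbations(rec)
        assert all(abs(e.pulse_time - target) > 1e-9 for e in events)

    def test_no_events_raises(self, recording):
        import dataclasses

        rec = dataclasses.replace(recording, onset_time_s=0.5)
        with pytest.raises(EmptySeriesError):
            locate_perturbations(rec)


class TestComputeMarkers:
    def test_saddle_node_trends_toward_bifurcation(self, sn_markers):
        rho_lam, rho_var = [], []
        for seed in range(3):
            ms = sn_markers if seed == 0 else cs.compute_markers(
                cs.simulate_saddle_node(cs.SDEConfig.saddle_node(seed=seed))
            )
            rho_lam.append(stats.spearmanr(ms.pulse_time, ms.lam).statistic)
            rho_var.append(stats.spearmanr(ms.pulse_time, ms.variance).statistic)
        assert np.median(rho_lam) < -0.8  # recovery slows down
        assert np.median(rho_var) > 0.6   # fluctuations grow

    def test_acf_increases(self, sn_markers):
        rho = stats.spearmanr(sn_markers.pulse_time, sn_markers.acf).statistic
        assert rho > 0.3

    def test_control_recording_is_flat(self, control_recording):
        ms = cs.compute_markers(control_recording)
        rho = stats.spearmanr(ms.pulse_time, ms.lam).statistic
        assert abs(rho) < 0.5  # ~3 sigma of the null for ~32 events

    def test_delta_I_is_distance_to_bifurcation(self, sn_markers, hopf_markers):
        assert np.all(np.diff(sn_markers.delta_I) < 0)
        assert sn_markers.delta_I[0] == pytest.approx(1.54)
        assert hopf_markers.delta_I[0] == pytest.approx(1.94)
        assert np.all(hopf_markers.delta_I[:-1] > 0)

    def test_recording_delta_I_uses_critical_current(self, recording_markers, recording):
        onset = recording.onset_time_s
        expected_ic = cs.critical_current(recording, onset)
        assert recording_markers.I_c == pytest.approx(expected_ic)
        assert recording_markers.V_cm is not None
        # the two pulses within one current step share the same pre-pulse
        # current, so delta_I is non-increasing and strictly drops per step
        diffs = np.diff(recording_markers.delta_I)
        assert np.all(diffs <= 1e-9)
        assert recording_markers.delta_I[0] > recording_markers.delta_I[-1]

    def test_empty_events_rejected(self, sn_trajectory):
        with pytest.raises(EmptySeriesError):
            cs.compute_markers(sn_trajectory, events=[])
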