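"""Widefield imaging chain: binning, filtering, correction, dF/F, metrics."""

import numpy as np
import pytest
from scipy import signal

from barrelquant import synthdata as sd
from barrelquant import widefield as wf

from conftest import center_roi


class TestSpatialBin:
    def test_paper_frame_size(self):
        stack = np.zeros((2, 880, 800))
        assert wf.spatial_bin(stack, 4).shape == (2, 220, 200)

    def test_constant_preserved(self):
        stack = np.full((3, 8, 8), 7.25)
        assert np.allclose(wf.spatial_bin(stack, 4), 7.25)

    def test_block_mean_8x8(self):
        frame = np.arange(64, dtype=float).reshape(1, 8, 8)
        out = wf.spatial_bin(frame, 4)
        assert out.shape == (1, 2, 2)
        assert out[0, 0, 0] == pytest.approx(13.5)

    def test_matches_bruteforce_random(self, rng):
        for _ in range(100):
            h, w = rng.integers(2, 9) * 2, rng.integers(2, 9) * 2
            stack = rng.normal(size=(2, h, w))
            out = wf.spatial_bin(stack, 2)
            # independent brute-force block means
            for t in range(2):
                for i in range(h // 2):
                    for j in range(w // 2):
                        blk = stack[t, 2 * i:2 * i + 2, 2 * j:2 * j + 2]
                        assert out[t, i, j] == pytest.approx(blk.mean())

    def test_global_mean_conserved(self, rng):
        stack = rng.normal(size=(3, 12, 16))
        assert wf.spatial_bin(stack, 4).mean() == pytest.approx(stack.mean())

    def test_trailing_crop(self):
        out = wf.spatial_bin(np.ones((1, 10, 11)), 4)
        assert out.shape == (1, 2, 2)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            wf.spatial_bin(np.ones((1, 4, 4)), 0)


class TestPreprocess:
    def test_linear_ramp_removed(self):
        fs = 30.0
        ramp = np.linspace(0.0, 100.0, 300)
        out = wf.preprocess_trace(ramp, fs)
        interior = out[30:-30]
        assert np.max(np.abs(interior)) < 1e-6 * 100.0

    def test_dc_removed(self):
        out = wf.preprocess_trace(np.full(300, 55.0), 30.0)
        assert np.max(np.abs(out)) < 1e-8

    def test_lowpass_attenuation_matches_transfer_function(self):
        # 20 Hz unit sinusoid sampled at 100 Hz; zero-phase application means
        # the attenuation is the squared single-pass magnitude response
        fs, f = 100.0, 20.0
        t = np.arange(3000) / fs
        x = np.sin(2 * np.pi * f * t)
        out = wf.preprocess_trace(x, fs)
        # RMS-based amplitude: max-of-samples misses the crest at this rate
        amp = np.sqrt(2 * np.mean(out[500:-500] ** 2))
        sos = signal.butter(2, 10.0, btype="lowpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[2 * np.pi * f / fs])
        assert amp == pytest.approx(np.abs(h[0]) ** 2, rel=0.02)

    def test_too_short(self):
        with pytest.raises(ValueError):
            wf.preprocess_trace(np.ones(2), 30.0)


class TestHemodynamicCorrect:
    def test_identical_channels_cancel(self, rng):
        s = rng.uniform(100, 200, size=(20, 4, 4))
        assert np.allclose(wf.hemodynamic_correct(s, s), 0.0, atol=1e-9)

    def test_scale_invariance_of_405(self, rng):
        s465 = rng.uniform(100, 200, size=(20, 3, 3))
        s405 = rng.uniform(100, 200, size=(20, 3, 3))
        ref = wf.hemodynamic_correct(s465, s405)
        for k in (0.1, 3.7):
            assert np.allclose(wf.hemodynamic_correct(s465, k * s405), ref, atol=1e-9)

    def test_proportional_hemo_pixels_cancel(self, rng):
        base = rng.uniform(100, 200, size=(50, 2, 2))
        assert np.allclose(wf.hemodynamic_correct(base, 0.8 * base), 0.0, atol=1e-9)

    def test_zero_405_pixel_masked(self):
        s465 = np.ones((5, 2, 2))
        s405 = np.ones((5, 2, 2))
        s405[:, 0, 0] = 0.0
        out = wf.hemodynamic_correct(s465, s405)
        assert np.isnan(out[:, 0, 0]).all()
        assert np.allclose(out[:, 1, 1], 0.0)


class TestDff:
    def test_constant_trace_is_zero(self):
        dff = wf.compute_dff(np.full(75, 42.0), 30.0, 0.5)
        assert np.allclose(dff, 0.0)

    def test_simple_ratio(self):
        trace = np.concatenate([np.full(15, 100.0), np.full(60, 150.0)])
        dff = wf.compute_dff(trace, 30.0, 0.5)
        assert dff[20] == pytest.approx(0.5)

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 80))
            fs = float(rng.uniform(10, 50))
            onset = float(rng.uniform(3, n - 3) / fs)
            trace = rng.uniform(50, 150, n)
            dff = wf.compute_dff(trace, fs, onset, pre_window=onset)
            t = np.arange(n) / fs
            f0 = trace[(t >= 0) & (t < onset)].mean()
            expected = (trace - f0) / f0
            assert np.allclose(dff, expected)

    def test_prewindow_mean_zero(self, rng):
        trace = rng.uniform(80, 120, 75)
        dff = wf.compute_dff(trace, 30.0, 0.5)
        t = np.arange(75) / 30.0
        assert dff[t < 0.5].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_baseline_errors(self):
        with pytest.raises(ZeroDivisionError):
            wf.compute_dff(np.zeros(75), 30.0, 0.5)


class TestTrialAverage:
    def test_identical_trials(self, rng):
        a = rng.normal(size=30)
        assert np.allclose(wf.trial_average([a, a, a]), a)

    def test_opposite_traces_cancel(self, rng):
        a = rng.normal(size=30)
        assert np.allclose(wf.trial_average([a, -a]), 0.0)

    def test_ragged_raises(self):
        with pytest.raises(ValueError):
            wf.trial_average([np.ones(10), np.ones(11)])

    def test_noise_shrinks_with_sqrt_n(self, rng):
        truth = np.sin(np.linspace(0, 3, 100))
        res = {}
        for n in (4, 256):
            trials = truth + rng.normal(0, 1.0, size=(n, 100))
            res[n] = np.sqrt(np.mean((wf.trial_average(trials) - truth) ** 2))
        # 64x more trials -> ~8x smaller residual
        assert res[4] / res[256] == pytest.approx(8.0, rel=0.5)


def _exp_transient_trace(tau=0.5, fs=30.0, onset=0.5, dur=2.5, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    dff = np.where(t >= onset, amp * np.exp(-(t - onset) / tau), 0.0)
    return wf.ResponseTrace(time=t, dff=dff, stimulus_onset=onset)


class TestResponseMetrics:
    def test_peak_and_latency_of_transient(self):
        m = wf.response_metrics(_exp_transient_trace())
        assert m.peak == pytest.approx(1.0)
        assert m.latency == pytest.approx(0.0, abs=1 / 30)

    def test_duration_closed_form(self):
        # time to decay to 20% of peak is tau*ln 5
        tau = 0.5
        m = wf.response_metrics(_exp_transient_trace(tau=tau))
        assert abs(m.duration - tau * np.log(5)) <= 1 / 30 + 1e-12

    def test_auc_matches_sample_sum(self):
        trace = _exp_transient_trace()
        m = wf.response_metrics(trace)
        i_on = np.searchsorted(trace.time, trace.stimulus_onset)
        i_end = np.searchsorted(trace.time, trace.stimulus_onset + m.duration)
        expected = trace.dff[i_on:i_end + 1].sum()
        assert m.auc == pytest.approx(expected)
        assert m.auc_norm == pytest.approx(m.auc)  # peak == 1

    def test_censored_when_never_below_20pct(self):
        t = np.arange(75) / 30.0
        dff = np.where(t >= 0.5, 1.0, 0.0)  # sustained plateau
        m = wf.response_metrics(wf.ResponseTrace(time=t, dff=dff, stimulus_onset=0.5))
        assert m.censored
        assert m.duration == pytest.approx(t[-1] - 0.5)

    def test_nonresponsive_flag(self):
        t = np.arange(75) / 30.0
        dff = np.where(t >= 0.5, -0.2, 0.0)
        m = wf.response_metrics(wf.ResponseTrace(time=t, dff=dff, stimulus_onset=0.5))
        assert not m.responsive


class TestActiveArea:
    def test_constant_projection_zero_area(self):
        stack = np.ones((10, 20, 20))
        assert wf.active_area(stack, 30.0, 0.1, 0.2) == 0.0

    def test_single_hot_pixel(self):
        stack = np.zeros((2, 220, 200))
        stack[1, 10, 10] = 1.0
        area = wf.active_area(stack, 30.0, 0.0, 1 / 30, pixel_size_um=30.0)
        assert area == pytest.approx(9e-4)

    def test_matches_bruteforce_threshold(self, rng):
        for _ in range(100):
            stack = rng.normal(0, 0.01, size=(5, 15, 15))
            yy, xx = np.mgrid[0:15, 0:15]
            stack[3] += 0.3 * np.exp(-((yy - 7) ** 2 + (xx - 7) ** 2) / 8.0)
            area = wf.active_area(stack, 30.0, 0.0, 4 / 30, pixel_size_um=30.0)
            proj = stack.max(axis=0)
            thr = proj.mean() + 2 * proj.std()
            assert area == pytest.approx(np.sum(proj > thr) * 0.03**2)

    def test_empty_range_errors(self):
        with pytest.raises(ValueError):
            wf.active_area(np.ones((10, 4, 4)), 30.0, 0.5, 0.4)


class TestSessionChain:
    def test_amplitude_and_tau_recovery(self, small_widefield_spec):
        trials, truth = sd.make_widefield_trials(small_widefield_spec)
        roi = center_roi((12, 12))
        m, trace, _ = wf.analyze_session(trials, roi_mask=roi, bin_factor=4)
        amp = truth.params["neural_amplitude"]
        tau = truth.params["neural_tau"]
        assert m.peak == pytest.approx(amp, rel=0.05)
        assert m.duration / np.log(5) == pytest.approx(tau, rel=0.10)

    def test_single_wavelength_mode(self, small_widefield_spec):
        trials, _ = sd.make_widefield_trials(small_widefield_spec)
        m, _, _ = wf.analyze_session(trials, bin_factor=4, correct=False)
        assert m.responsive

    def test_deterministic(self, small_widefield_spec):
        trials, _ = sd.make_widefield_trials(small_widefield_spec)
        m1, t1, _ = wf.analyze_session(trials, bin_factor=4)
        m2, t2, _ = wf.analyze_session(trials, bin_factor=4)
        assert m1.as_dict() == m2.as_dict()
        assert np.array_equal(t1.dff, t2.dff)
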