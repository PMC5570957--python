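"""Quantification: tracking, extraction, bleach correction, transient metrics."""

import numpy as np
import pytest

import fretscreen as fs
from fretscreen.fret import QuantConfig, metrics_from_ideal
from fretscreen.regions import Rect
from fretscreen.scene import NoiseConfig


def make_trace(t, ratio, base=1000.0, t_on=40.0, t_off=70.0) -> fs.FretTrace:
    """Trace whose acceptor/donor equals ``ratio`` exactly."""
    ratio = np.asarray(ratio, dtype=float)
    return fs.FretTrace(t, base / (1 + ratio), base * ratio / (1 + ratio),
                        t_on=t_on, t_off=t_off)


class TestTracking:
    def test_static_neuron_constant_path(self, timing, det_config):
        scene = fs.SceneParams(z_true_um=50.0)
        _, series, _ = fs.simulate_worm_session(
            scene, timing.kinetics(), fs.BleachModel(), timing, noise=None
        )
        pos, lost = fs.track_neuron(series, (int(scene.neuron_x), int(scene.neuron_y)),
                                    det_config)
        assert not lost.any()
        assert np.ptp(pos, axis=0).max() == 0

    def test_linear_drift_recovered(self, det_config):
        """A spot drifting 1 px/frame is followed within 1 px RMS."""
        from fretscreen.scene import _gaussian_spot

        n = 40
        frames = []
        xs = 30.0 + np.arange(n) * 1.0
        for i in range(n):
            img = np.full((100, 160), 100.0)
            img += _gaussian_spot((100, 160), xs[i], 50.0, 2.0, 1500.0)
            frames.append(img)
        stack = fs.ChannelStack(np.stack(frames), np.stack(frames), axis="time",
                                frame_interval_s=0.5)
        pos, lost = fs.track_neuron(stack, (30, 50), det_config)
        assert not lost.any()
        rms = np.sqrt(np.mean((pos[:, 0] - xs) ** 2))
        assert rms <= 1.0

    def test_vanishing_neuron_flags_frames(self, det_config):
        from fretscreen.scene import _gaussian_spot

        frames = []
        for i in range(20):
            img = np.full((100, 160), 100.0)
            if i < 10:
                img += _gaussian_spot((100, 160), 30.0, 50.0, 2.0, 1500.0)
            frames.append(img)
        stack = fs.ChannelStack(np.stack(frames), np.stack(frames), axis="time",
                                frame_interval_s=0.5)
        pos, lost = fs.track_neuron(stack, (30, 50), det_config)
        assert not lost[:10].any()
        assert lost[10:].all()
        assert np.all(pos[10:] == pos[9])   # last good position held


class TestExtractTrace:
    def test_uniform_image_gives_zero_net_intensity(self):
        frames = np.full((10, 100, 160), 150.0)
        stack = fs.ChannelStack(frames, frames, axis="time", frame_interval_s=0.5)
        pos = np.tile([80, 50], (10, 1))
        trace = fs.extract_trace(stack, pos, 3, Rect(4, 4, 36, 24), 2.0, 4.0)
        assert np.allclose(trace.donor, 0.0) and np.allclose(trace.acceptor, 0.0)
        assert not trace.frame_ok.any()

    def test_extracted_ratio_matches_generator(self, timing, geom, det_config):
        scene = fs.SceneParams(z_true_um=50.0)
        k = timing.kinetics(amplitude=0.3)
        _, series, _ = fs.simulate_worm_session(scene, k, fs.BleachModel(0, 0),
                                                timing, noise=None)
        pos = np.tile([int(scene.neuron_x), int(scene.neuron_y)], (series.n_frames, 1))
        trace = fs.extract_trace(series, pos, 3, geom.background_region(),
                                 timing.t_on, timing.t_off)
        ratio = trace.acceptor / trace.donor
        np.testing.assert_allclose(ratio, fs.ideal_ratio(k, timing.times()), rtol=1e-6)

    def test_roi_must_stay_inside_image(self):
        frames = np.full((5, 50, 50), 10.0)
        stack = fs.ChannelStack(frames, frames, axis="time", frame_interval_s=0.5)
        pos = np.tile([1, 1], (5, 1))
        with pytest.raises(ValueError):
            fs.extract_trace(stack, pos, 3, Rect(20, 20, 40, 40), 1.0, 2.0)


class TestBleachCorrection:
    def test_no_bleach_is_identity(self, timing):
        k = timing.kinetics(amplitude=0.3)
        t, d, a = fs.simulate_trace(k, fs.BleachModel(0, 0), timing, noise_rel=0)
        trace = fs.correct_bleach(fs.FretTrace(t, d, a, t_on=40, t_off=70))
        np.testing.assert_allclose(trace.donor_corr, d, rtol=1e-9)
        np.testing.assert_allclose(trace.acceptor_corr, a, rtol=1e-9)

    @pytest.mark.parametrize("ld,la", [(0.005, 0.002), (0.01, 0.0), (0.0, 0.01)])
    def test_null_response_flattened(self, timing, ld, la):
        k = timing.kinetics(amplitude=0.0)
        t, d, a = fs.simulate_trace(k, fs.BleachModel(ld, la), timing, noise_rel=0)
        trace = fs.FretTrace(t, d, a, t_on=40, t_off=70)
        fs.correct_bleach(trace)
        fs.percent_change(trace)
        assert np.abs(trace.dr_pct).max() < 0.5

    def test_lambda_recovered_on_pure_decay(self, timing):
        k = timing.kinetics(amplitude=0.0)
        t, d, a = fs.simulate_trace(k, fs.BleachModel(0.0043, 0.0017), timing, noise_rel=0)
        trace = fs.correct_bleach(fs.FretTrace(t, d, a, t_on=40, t_off=70))
        ld, la = trace.lambda_hat
        assert ld == pytest.approx(0.0043, rel=1e-6)
        assert la == pytest.approx(0.0017, rel=1e-6)

    def test_flatness_at_default_noise(self, timing):
        """Corrected null-response traces stay within 3% RMS at the default noise."""
        rng = np.random.default_rng(20)
        k = timing.kinetics(amplitude=0.0)
        rms = []
        for _ in range(20):
            t, d, a = fs.simulate_trace(k, fs.BleachModel(0.008, 0.003), timing,
                                        noise_rel=0.02, rng=rng)
            trace = fs.FretTrace(t, d, a, t_on=40, t_off=70)
            fs.correct_bleach(trace)
            fs.percent_change(trace)
            rms.append(np.sqrt(np.mean(trace.dr_pct**2)))
        assert np.median(rms) < 3.0

    def test_short_baseline_rejected(self):
        t = np.arange(0, 10, 0.5)
        trace = fs.FretTrace(t, np.full_like(t, 10.0), np.full_like(t, 15.0),
                             t_on=1.0, t_off=2.0)
        with pytest.raises(ValueError):
            fs.correct_bleach(trace, QuantConfig(t_on=1.0, t_off=2.0,
                                                 baseline_window=(0.0, 1.0),
                                                 bleach_window=(0.0, 1.0)))


class TestPercentChange:
    def test_constant_series(self, timing):
        t = timing.times()
        trace = make_trace(t, np.full_like(t, 1.8))
        fs.correct_bleach(trace)
        fs.percent_change(trace)
        assert trace.baseline_ratio == pytest.approx(1.8, rel=1e-9)
        assert np.abs(trace.dr_pct).max() < 1e-9

    def test_doubling_is_hundred_percent(self, timing):
        t = timing.times()
        ratio = np.where(t >= 40.0, 2.0, 1.0)
        trace = make_trace(t, ratio)
        fs.correct_bleach(trace)
        fs.percent_change(trace)
        assert trace.dr_pct[t >= 40.0].max() == pytest.approx(100.0, rel=1e-9)

    def test_closed_form_peak(self, timing):
        k = timing.kinetics(amplitude=0.3, tau_rise=5.0)
        t, d, a = fs.simulate_trace(k, fs.BleachModel(0, 0), timing, noise_rel=0)
        trace = fs.FretTrace(t, d, a, t_on=40, t_off=70)
        fs.correct_bleach(trace)
        fs.percent_change(trace)
        expected = 30.0 * (1 - np.exp(-6.0))
        assert trace.dr_pct.max() == pytest.approx(expected, rel=1e-6)


class TestRisingPhaseAndMetrics:
    def test_plateau_peak_is_earliest_maximum(self):
        t = np.arange(0, 90, 0.5)
        dr = np.where(t >= 50.0, 20.0, np.where(t >= 40.0, 2.0 * (t - 40.0), 0.0))
        onset, peak = fs.rising_phase(dr, t, 40.0, 70.0)
        assert t[peak] == 50.0          # start of the plateau, not a later tie
        assert t[onset] <= 41.5

    def test_flat_series_is_non_responder(self, timing):
        t = timing.times()
        trace = make_trace(t, np.full_like(t, 1.5))
        m = fs.quantify_trace(trace)
        assert m.peak_pct == 0.0 and m.slope_pct_s == 0.0 and not m.responder
        assert m.onset_idx == m.peak_idx

    def test_simulated_transient_peak_index(self, timing):
        k = timing.kinetics(amplitude=0.4)
        t, d, a = fs.simulate_trace(k, fs.BleachModel(0, 0), timing, noise_rel=0)
        m = fs.quantify_trace(fs.FretTrace(t, d, a, t_on=40, t_off=70))
        # the ideal ratio peaks at stimulus offset (70 s); the smoothed argmax
        # may sit up to half the boxcar width earlier
        assert abs(t[m.peak_idx] - 70.0) <= 3.0
        assert m.peak_idx >= m.onset_idx

    def test_linear_ramp_metrics(self):
        """0 -> 20% over 10 s then hold: peak 20%, slope 2 %/s."""
        t = np.arange(0, 90, 0.5)
        dr = np.clip((t - 40.0) * 2.0, 0.0, 20.0)
        ratio = 1.5 * (1 + dr / 100.0)
        trace = make_trace(t, ratio)
        m = fs.quantify_trace(trace)
        assert m.peak_pct == pytest.approx(20.0, rel=0.02)
        assert m.slope_pct_s == pytest.approx(2.0, rel=0.05)

    def test_peak_matches_closed_form_across_amplitudes(self, timing):
        for a in np.linspace(0.05, 0.6, 12):
            k = timing.kinetics(amplitude=float(a))
            t, d, acc = fs.simulate_trace(k, fs.BleachModel(0, 0), timing, noise_rel=0)
            m = fs.quantify_trace(fs.FretTrace(t, d, acc, t_on=40, t_off=70))
            assert m.peak_pct == pytest.approx(fs.ideal_peak_pct(k), rel=0.05)

    def test_scale_invariance(self, timing):
        k = timing.kinetics(amplitude=0.25)
        t, d, a = fs.simulate_trace(k, fs.BleachModel(), timing, noise_rel=0)
        m1 = fs.quantify_trace(fs.FretTrace(t, d, a, t_on=40, t_off=70))
        m2 = fs.quantify_trace(fs.FretTrace(t, 13.7 * d, 13.7 * a, t_on=40, t_off=70))
        assert abs(m1.peak_pct - m2.peak_pct) < 1e-9
        assert abs(m1.slope_pct_s - m2.slope_pct_s) < 1e-9

    def test_peak_monotone_in_amplitude(self, timing):
        peaks = []
        for a in np.linspace(0.02, 0.6, 20):
            k = timing.kinetics(amplitude=float(a))
            t, d, acc = fs.simulate_trace(k, fs.BleachModel(0, 0), timing, noise_rel=0)
            peaks.append(fs.quantify_trace(fs.FretTrace(t, d, acc, t_on=40, t_off=70)).peak_pct)
        assert np.all(np.diff(peaks) >= 0)

    def test_ideal_estimand_scales_linearly(self, timing):
        m1 = metrics_from_ideal(timing.kinetics(amplitude=0.2), timing)
        m2 = metrics_from_ideal(timing.kinetics(amplitude=0.4), timing)
        assert m2.peak_pct == pytest.approx(2 * m1.peak_pct, rel=1e-9)
        assert m2.slope_pct_s == pytest.approx(2 * m1.slope_pct_s, rel=1e-9)
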