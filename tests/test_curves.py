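"""Curve extraction, smoothing, time-to-signal, slope_max, segmentation."""

import numpy as np
import pytest

import nirfperf as nf
from nirfperf.core import Roi
from tests.conftest import make_curve


class TestExtractRoiCurve:
    def test_single_pixel_roi_equals_raw_series(self, success_run):
        _, stack, _, _ = success_run
        mask = np.zeros(stack.frame_shape, dtype=bool)
        mask[20, 10] = True
        curve = nf.extract_roi_curve(stack, Roi(label="1", role="muscle", mask=mask))
        assert np.array_equal(curve.intensities, stack.frames[:, 20, 10])

    def test_uniform_frames_give_constant_curve(self):
        times = np.arange(20) * 0.5
        frames = np.full((20, 5, 5), 4.25)
        stack = nf.FrameStack(frames=frames, timestamps=times)
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 2:5] = True
        curve = nf.extract_roi_curve(stack, Roi(label="2", role="muscle", mask=mask))
        assert np.allclose(curve.intensities, 4.25)

    def test_noiseless_uniform_region_matches_analytic_curve(self):
        mask = np.ones((5, 5), dtype=bool)
        cfg = nf.SimulationConfig(
            frame_shape=(5, 5), duration_s=100, fps=2.0, noise_sd=0.0,
            muscle_mask=mask, gradient=(1.0, 1.0),
            axis_base=(2.0, 0.0), axis_tip=(2.0, 5.0), seed=0,
        )
        stack, _ = nf.generate_video(cfg)
        curve = nf.extract_roi_curve(stack, Roi(label="1", role="muscle", mask=mask))
        assert np.allclose(
            curve.intensities, nf.pixel_curve(cfg.muscle_kinetics, stack.timestamps), atol=1e-10
        )

    def test_union_of_equal_rois_averages_their_curves(self, success_run):
        _, stack, _, _ = success_run
        m1 = np.zeros(stack.frame_shape, dtype=bool)
        m2 = np.zeros(stack.frame_shape, dtype=bool)
        m1[10:14, 10:14] = True
        m2[20:24, 30:34] = True  # disjoint, same size
        c1 = nf.extract_roi_curve(stack, Roi(label="1", role="muscle", mask=m1))
        c2 = nf.extract_roi_curve(stack, Roi(label="2", role="muscle", mask=m2))
        cu = nf.extract_roi_curve(stack, Roi(label="3", role="muscle", mask=m1 | m2))
        assert np.allclose(cu.intensities, (c1.intensities + c2.intensities) / 2, atol=1e-10)

    def test_empty_roi_rejected(self, ramp_stack):
        mask = np.zeros(ramp_stack.frame_shape, dtype=bool)
        roi = Roi(label="1", role="muscle", mask=mask)
        with pytest.raises(ValueError, match="empty"):
            nf.extract_roi_curve(ramp_stack, roi)


class TestSmoothCurve:
    def test_zero_window_is_identity(self):
        curve = make_curve(np.arange(20.0), np.sin(np.arange(20.0)) + 2)
        out = nf.smooth_curve(curve, 0.0)
        assert np.array_equal(out.intensities, curve.intensities)

    def test_constant_curve_unchanged(self):
        curve = make_curve(np.arange(30.0), np.full(30, 3.0))
        for w in (1.0, 5.0, 11.0):
            assert np.allclose(nf.smooth_curve(curve, w).intensities, 3.0)

    def test_white_noise_variance_reduced_by_window_length(self):
        rng = np.random.default_rng(42)
        times = np.arange(4000) * 1.0
        curve = make_curve(times, rng.normal(0, 1, 4000))
        out = nf.smooth_curve(curve, 4.0)  # 5 samples per window at 1 Hz
        interior = out.intensities[5:-5]
        assert np.var(interior) == pytest.approx(1 / 5, rel=0.15)

    def test_window_longer_than_record_rejected(self):
        curve = make_curve(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError, match="longer than the record"):
            nf.smooth_curve(curve, 100.0)


class TestTimeToSignal:
    def test_constant_curve_has_no_signal(self, config):
        curve = make_curve(np.arange(50.0), np.full(50, 2.0))
        assert nf.time_to_signal(curve, config) is None

    def test_noiseless_step_detected_at_step_time(self, config):
        times = np.arange(0, 40, 0.5)
        y = np.where(times >= 12.0, 10.0, 0.0)
        curve = make_curve(times, y, baseline_n=10)
        assert nf.time_to_signal(curve, config) == 12.0

    def test_simulated_onset_recovered_within_smoothing_window(self, success_run, config):
        cfg, stack, _, rois = success_run
        for roi in rois.muscle_rois:
            curve = nf.extract_roi_curve(stack, roi, config)
            tts = nf.time_to_signal(curve, config)
            assert tts is not None
            assert abs(tts - cfg.muscle_kinetics.t0) <= config.smoothing_window_s

    def test_degenerate_baseline_rejected(self, config):
        curve = nf.PerfusionCurve(
            times=np.arange(5.0), intensities=np.arange(5.0), baseline_n=1
        )
        with pytest.raises(ValueError, match="degenerate baseline"):
            nf.time_to_signal(curve, config)


class TestComputeSlopeMax:
    def test_linear_ramp_exact(self, config):
        times = np.arange(0, 20, 0.25)
        curve = make_curve(times, 3.0 * times)
        smax, _ = nf.compute_slope_max(curve, config)
        assert smax == pytest.approx(3.0, abs=1e-9)

    def test_constant_curve_zero(self, config):
        curve = make_curve(np.arange(30.0), np.full(30, 5.0))
        smax, _ = nf.compute_slope_max(curve, config)
        assert smax == pytest.approx(0.0, abs=1e-12)

    def test_intensity_scaling_scales_slope(self, config):
        rng = np.random.default_rng(7)
        times = np.arange(0, 60, 0.5)
        y = np.cumsum(rng.uniform(0, 1, len(times)))
        s1, t1 = nf.compute_slope_max(make_curve(times, y), config)
        s2, t2 = nf.compute_slope_max(make_curve(times, 3.5 * y), config)
        s3, t3 = nf.compute_slope_max(make_curve(times, y + 100.0), config)
        assert s2 == pytest.approx(3.5 * s1, rel=1e-9)
        assert s3 == pytest.approx(s1, rel=1e-9)
        assert t1 == t2 == t3

    def test_time_shift_shifts_t_slope_max_only(self, config):
        p = nf.KineticParams()
        times = np.arange(0, 100, 0.5)
        y = nf.pixel_curve(p, times)
        s1, t1 = nf.compute_slope_max(make_curve(times, y), config)
        s2, t2 = nf.compute_slope_max(make_curve(times + 17.0, y), config)
        assert s2 == pytest.approx(s1, rel=1e-9)
        assert t2 == pytest.approx(t1 + 17.0, abs=1e-9)

    def test_noiseless_sampled_curve_matches_analytic_oracle(self, config):
        p = nf.KineticParams()
        times = np.arange(0, 80, 0.5)
        curve = make_curve(times, nf.pixel_curve(p, times))
        smax, t_smax = nf.compute_slope_max(curve, config)
        assert smax == pytest.approx(nf.analytic_slope_max(p), rel=0.02)
        t_star = p.t0 + p.t_peak_offset * (1 - 1 / np.sqrt(p.alpha))
        assert t_smax == pytest.approx(t_star, abs=1.0)

    def test_curve_shorter_than_window_rejected(self, config):
        curve = make_curve([0.0, 0.5, 1.0], [0.0, 1.0, 2.0], baseline_n=2)
        with pytest.raises(ValueError, match="shorter than the slope window"):
            nf.compute_slope_max(curve, config)


class TestSegmentPhases:
    def _features(self, w, config):
        p = nf.KineticParams(washout_fraction=w)
        times = np.arange(0, 120, 0.5)
        return nf.curve_features(make_curve(times, nf.pixel_curve(p, times), baseline_n=20), config)

    def test_full_washout_has_ingress_and_egress(self, config):
        f = self._features(1.0, config)
        assert f.has_ingress and f.has_egress and not f.plateau_flag

    def test_no_washout_has_ingress_but_no_egress(self, config):
        f = self._features(0.0, config)
        assert f.has_ingress and not f.has_egress
        assert f.plateau_flag

    def test_constant_curve_all_absent(self, config):
        curve = make_curve(np.arange(60.0), np.full(60, 2.0))
        seg = nf.segment_phases(curve, config)
        assert seg.ingress_interval is None
        assert seg.egress_interval is None
        assert not seg.plateau_flag
        f = nf.curve_features(curve, config)
        assert not f.has_ingress and not f.has_egress
        assert f.slope_max == pytest.approx(0.0, abs=1e-12)
        assert f.time_to_signal is None

    def test_intervals_ordered_within_record(self, config):
        p = nf.KineticParams()
        times = np.arange(0, 120, 0.5)
        curve = nf.smooth_curve(
            make_curve(times, nf.pixel_curve(p, times), baseline_n=20),
            config.smoothing_window_s,
        )
        seg = nf.segment_phases(curve, config)
        (i0, i1), (e0, e1) = seg.ingress_interval, seg.egress_interval
        assert times[0] <= i0 <= i1 == e0 <= e1 <= times[-1]

    def test_simulated_phenotype_flags_recovered(self, success_run, failed_run, config):
        for run, want_egress in ((success_run, True), (failed_run, False)):
            cfg, stack, truth, rois = run
            for roi in rois.muscle_rois:
                mask = nf.rasterize_roi(roi, cfg.frame_shape)
                f = nf.curve_features(nf.extract_roi_curve(stack, roi, config), config)
                true_ingress = truth.true_has_ingress[mask].any()
                assert f.has_ingress == true_ingress
                if true_ingress:
                    assert f.has_egress == want_egress
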