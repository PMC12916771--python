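import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselperm import leakage, synth
from vesselperm.stack import FrameStack

from conftest import iv_tot_from_scene, scene_rois


def constant_trace(value=1.0, n=121, dt=30.0):
    return leakage.IntensityTrace(times=np.arange(n) * dt, values=np.full(n, value))


class TestExtractTrace:
    def test_uniform_frame(self):
        stack = FrameStack(
            pixels=np.full((3, 1, 10, 10), 9.0), pixel_size=1.0, frame_interval=1.0
        )
        roi = leakage.ROISpec("rectangle", (2, 2, 4, 4))
        trace = leakage.extract_trace(stack, roi, 0)
        assert np.all(trace.values == 9.0)

    def test_small_roi_mean(self):
        pixels = np.zeros((1, 1, 4, 4))
        pixels[0, 0, :2, :2] = [[1, 2], [3, 4]]
        stack = FrameStack(pixels=pixels, pixel_size=1.0, frame_interval=1.0)
        trace = leakage.extract_trace(stack, leakage.ROISpec("rectangle", (0, 0, 2, 2)), 0)
        assert trace.values[0] == pytest.approx(2.5)

    def test_out_of_bounds(self):
        stack = FrameStack(
            pixels=np.zeros((1, 1, 10, 10)), pixel_size=1.0, frame_interval=1.0
        )
        with pytest.raises(ValueError, match="outside image"):
            leakage.extract_trace(stack, leakage.ROISpec("rectangle", (8, 8, 5, 5)), 0)

    def test_matches_generator_law(self, hypo_scene, hypo_movie):
        stack, _ = hypo_movie
        reg = hypo_scene.perivascular_region
        roi = leakage.ROISpec("rectangle", reg.rect)
        trace = leakage.extract_trace(stack, roi, 0)
        expected = (
            hypo_scene.noise.background_offset
            + reg.baseline
            + reg.mean_excess_at(stack.times, hypo_scene.switch_time)
        )
        assert np.allclose(trace.values, expected, rtol=1e-6)


class TestBackgroundCorrect:
    def test_subtraction(self):
        t = constant_trace(10.0, n=5, dt=1.0)
        b = constant_trace(3.0, n=5, dt=1.0)
        out = leakage.background_correct(t, b)
        assert np.all(out.values == 7.0)
        assert out.background_corrected

    def test_negatives_retained(self):
        t = constant_trace(10.0, n=3, dt=1.0)
        b = leakage.IntensityTrace(times=[0, 1, 2], values=[3.0, 15.0, 3.0])
        out = leakage.background_correct(t, b)
        assert out.values[1] == -5.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            leakage.background_correct(constant_trace(n=3, dt=1.0), constant_trace(n=4, dt=1.0))


class TestNormalizeBaseline:
    def test_constant_becomes_ones(self):
        norm = leakage.normalize_baseline(constant_trace(42.0))
        assert np.allclose(norm.values, 1.0)

    def test_step_doubles(self):
        values = np.where(np.arange(121) < 10, 5.0, 10.0)
        trace = leakage.IntensityTrace(times=np.arange(121) * 30.0, values=values)
        norm = leakage.normalize_baseline(trace)
        assert norm.values[-1] == pytest.approx(2.0)
        assert norm.baseline_window == (0.0, 270.0)

    def test_default_window_spans_ten_frames(self):
        norm = leakage.normalize_baseline(constant_trace())
        assert leakage.n_baseline_frames(norm) == 10

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline mean"):
            leakage.normalize_baseline(constant_trace(0.0))

    @given(
        baseline=st.floats(0.1, 1e4),
        scale=st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, baseline, scale):
        rng = np.random.default_rng(0)
        values = baseline * (1 + 0.1 * rng.uniform(size=30)) * scale
        trace = leakage.IntensityTrace(times=np.arange(30) * 30.0, values=values)
        once = leakage.normalize_baseline(trace)
        twice = leakage.normalize_baseline(
            leakage.IntensityTrace(times=once.times, values=once.values)
        )
        assert np.allclose(once.values, twice.values, rtol=1e-12)


class TestIntegrateLeakage:
    def test_constant_is_3600(self):
        norm = leakage.normalize_baseline(constant_trace(7.0))
        assert leakage.integrate_leakage(norm) == 3600.0

    def test_hand_trapezoid_step(self):
        # frames 0-9 = 1, frames 10-120 = 2:
        # 9*30*1 + 30*1.5 + 110*30*2 = 6915
        values = np.where(np.arange(121) < 10, 1.0, 2.0)
        norm = leakage.NormalizedTrace(
            times=np.arange(121) * 30.0, values=values, baseline_window=(0.0, 270.0)
        )
        assert leakage.integrate_leakage(norm) == pytest.approx(6915.0)

    def test_empty_window(self):
        norm = leakage.normalize_baseline(constant_trace())
        assert leakage.integrate_leakage(norm, window=(0.0, 0.0)) == 0.0

    def test_uncovered_window(self):
        norm = leakage.normalize_baseline(constant_trace(n=10, dt=30.0))
        with pytest.raises(ValueError, match="not covered"):
            leakage.integrate_leakage(norm, window=(0.0, 3600.0))

    def test_trapezoid_vs_oversampled_riemann(self, hypo_scene):
        # oracle: 100x oversampled integration of the generator's analytic law
        reg = hypo_scene.perivascular_region
        times = hypo_scene.times

        def law(t):
            return (reg.baseline + reg.mean_excess_at(t, hypo_scene.switch_time)) / reg.baseline

        norm = leakage.NormalizedTrace(
            times=times, values=law(times), baseline_window=(0.0, 270.0)
        )
        got = leakage.integrate_leakage(norm)
        fine = np.linspace(0, 3600, 121 * 100 + 1)
        oracle = np.trapezoid(law(fine), fine)
        assert got == pytest.approx(oracle, rel=1e-3)


class TestLeakageRate:
    def test_constant_zero(self):
        norm = leakage.normalize_baseline(constant_trace())
        rate, peak, _ = leakage.leakage_rate(norm)
        assert np.all(rate == 0)
        assert peak == 0

    def test_linear_ramp_exact(self):
        times = np.arange(50) * 10.0
        trace = leakage.IntensityTrace(times=times, values=1.0 + 0.01 * times)
        rate, peak, _ = leakage.leakage_rate(trace)
        assert np.allclose(rate, 0.01)

    def test_sat_exp_peak_near_switch(self, hypo_scene):
        # analytic argmax of d/dt[A(1-exp(-(t-ts)/tau))] is at ts
        reg = hypo_scene.perivascular_region
        times = hypo_scene.times
        values = 1 + reg.mean_excess_at(times, hypo_scene.switch_time) / reg.baseline
        trace = leakage.IntensityTrace(times=times, values=values)
        _, _, peak_time = leakage.leakage_rate(trace)
        assert abs(peak_time - hypo_scene.switch_time) <= hypo_scene.frame_interval

    def test_too_few_frames(self):
        with pytest.raises(ValueError, match="3 frames"):
            leakage.leakage_rate(constant_trace(n=2, dt=1.0))


class TestBlockadePercent:
    def test_full_block(self):
        assert leakage.blockade_percent(3600.0, 3700.0) == pytest.approx(100.0)

    def test_no_block(self):
        assert leakage.blockade_percent(3700.0, 3700.0) == pytest.approx(0.0)

    def test_hand_value_88(self):
        # 100 * (1 - 3/25)
        assert leakage.blockade_percent(3603.0, 3625.0) == pytest.approx(88.0)

    def test_undefined_for_control_at_baseline(self):
        with pytest.raises(ValueError, match="control"):
            leakage.blockade_percent(3600.0, 3600.0)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_treated(self, excess_a, excess_b):
        lo, hi = sorted((excess_a, excess_b))
        if hi - lo < 1e-9:
            return
        control = 3600.0 + 50.0
        assert leakage.blockade_percent(3600 + lo, control) > leakage.blockade_percent(
            3600 + hi, control
        )


class TestKymograph:
    def test_column_count_is_frame_count(self, hypo_scene, hypo_movie):
        stack, _ = hypo_movie
        line = scene_rois(hypo_scene)["dilation_line"]
        kymo = leakage.build_kymograph(stack, line, 0)
        assert kymo.n_frames == 121

    def test_static_band_columns_identical(self, no_wound_scene):
        stack, _ = synth.render_movie(no_wound_scene)
        line = scene_rois(no_wound_scene)["dilation_line"]
        kymo = leakage.build_kymograph(stack, line, 0)
        assert np.allclose(kymo.matrix, kymo.matrix[:, :1])

    def test_band_widens_after_switch(self, hypo_scene, hypo_movie):
        stack, _ = hypo_movie
        line = scene_rois(hypo_scene)["dilation_line"]
        kymo = leakage.build_kymograph(stack, line, 0)
        thr = (kymo.matrix.max() + kymo.matrix.min()) / 2
        runs = (kymo.matrix > thr).sum(axis=0)
        assert runs[-1] > runs[0]


class TestVesselDiameter:
    def _band_kymo(self, widths, n_pos=51, pixel_size=0.65):
        mat = np.zeros((n_pos, len(widths)))
        mid = n_pos // 2
        for k, w in enumerate(widths):
            half = w // 2
            mat[mid - half : mid - half + w, k] = 100.0
        return leakage.Kymograph(matrix=mat, pixel_size=pixel_size, frame_interval=30.0)

    def test_constant_width(self):
        kymo = self._band_kymo([20] * 5)
        dv = leakage.vessel_diameter(kymo)
        assert np.allclose(dv.values, 20 * 0.65)
        assert dv.values[0] == pytest.approx(13.0)

    def test_longest_run_rule(self):
        mat = np.zeros((40, 3))
        mat[2:7, :] = 100.0  # run of 5
        mat[20:32, :] = 100.0  # run of 12
        kymo = leakage.Kymograph(matrix=mat, pixel_size=1.0, frame_interval=30.0)
        dv = leakage.vessel_diameter(kymo)
        assert np.all(dv.values == 12.0)
        dv_count = leakage.vessel_diameter(kymo, run_mode="count")
        assert np.all(dv_count.values == 17.0)

    def test_background_column_zero(self):
        mat = np.zeros((40, 4))
        mat[10:30, :2] = 100.0  # frames 2,3 all background
        kymo = leakage.Kymograph(matrix=mat, pixel_size=1.0, frame_interval=30.0)
        dv = leakage.vessel_diameter(kymo)
        assert dv.values[2] == 0.0

    def test_flat_kymograph_errors(self):
        kymo = leakage.Kymograph(matrix=np.ones((10, 5)), pixel_size=1.0, frame_interval=1.0)
        with pytest.raises(ValueError, match="flat"):
            leakage.vessel_diameter(kymo)


class TestMaxDilation:
    def test_constant_is_one(self):
        dv = constant_trace(10.0)
        assert leakage.max_dilation(leakage.normalize_baseline(dv)) == pytest.approx(1.0)

    def test_peak_ratio(self):
        values = np.full(121, 10.0)
        values[60] = 14.0
        trace = leakage.IntensityTrace(times=np.arange(121) * 30.0, values=values)
        assert leakage.max_dilation(leakage.normalize_baseline(trace)) == pytest.approx(1.4)

    def test_monotone_decreasing_max_in_baseline(self):
        values = np.linspace(20, 10, 121)
        trace = leakage.IntensityTrace(times=np.arange(121) * 30.0, values=values)
        norm = leakage.normalize_baseline(trace)
        assert leakage.max_dilation(norm) == pytest.approx(norm.values[0])


class TestKymoArea:
    def test_half_mask_area(self):
        mat = np.zeros((100, 121))
        mat[:50, :] = 100.0
        kymo = leakage.Kymograph(matrix=mat, pixel_size=1.0, frame_interval=30.0)
        area_px, area_um2, _ = leakage.kymo_area(kymo)
        assert area_px == 6050
        assert area_um2 == pytest.approx(6050.0)

    def test_fov_conversion(self):
        # 1024 px * 0.65 µm/px = 665.6 µm per side -> 4.43e5 µm²
        assert leakage.fov_area_um2((1024, 1024), 0.65) == pytest.approx(4.43e5, rel=1e-3)

    def test_onset_detection(self):
        rng = np.random.default_rng(0)
        mat = np.full((60, 121), 10.0) + rng.normal(0, 0.05, size=(60, 121))
        mat[:, 20:] += 50.0  # leakage begins at frame 20 (t = 600 s)
        kymo = leakage.Kymograph(matrix=mat, pixel_size=1.0, frame_interval=30.0)
        _, _, onset = leakage.kymo_area(kymo)
        assert onset is not None
        assert abs(onset - 600.0) <= 60.0

    def test_no_onset_when_flat_trend(self):
        rng = np.random.default_rng(1)
        mat = np.full((60, 40), 10.0) + rng.normal(0, 0.05, size=(60, 40))
        kymo = leakage.Kymograph(matrix=mat, pixel_size=1.0, frame_interval=30.0)
        *_, onset = leakage.kymo_area(kymo)
        assert onset is None


class TestEndToEnd:
    def test_baseline_identity_with_noise(self):
        # no-leakage scene at SNR >= 20 -> 3600 ± 1 and max dilation 1 ± 0.02
        # read-noise chosen so the ROI-mean noise matches paper-sized ROIs at SNR 20
        scene = synth.make_scene("no_wound", noise=synth.NoiseSpec(0.0, 0.3, 10.0), seed=11)
        iv = iv_tot_from_scene(scene)
        assert iv == pytest.approx(3600.0, abs=1.0)

        stack, _ = synth.render_movie(scene)
        line = scene_rois(scene)["dilation_line"]
        kymo = leakage.build_kymograph(stack, line, 0)
        dv = leakage.vessel_diameter(kymo)
        assert leakage.max_dilation(leakage.normalize_baseline(dv)) == pytest.approx(
            1.0, abs=0.02
        )

    def test_blockade_recovery_within_one_percent(self):
        control, treated = synth.blockade_pair(control_auc=25.0, treated_auc=3.0)
        got = leakage.blockade_percent(
            iv_tot_from_scene(treated), iv_tot_from_scene(control)
        )
        assert got == pytest.approx(88.0, rel=0.01)
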