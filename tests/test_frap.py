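import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condensate import frap
from condensate import synth_data as sd
from condensate.exceptions import FitError, GeometryError, NormalizationError
from condensate.io_formats import CircleRoi, LineRoi, TimelapseStack


def make_trace(tau, plateau, i0, n_frames=50, dt=0.2, bleach_frame=5, noise=None, seed=0):
    """Closed-form recovery trace, optionally with Gaussian noise (pct points)."""
    t = (np.arange(n_frames) - bleach_frame) * dt
    y = np.where(t >= 0, frap.exponential_recovery(np.clip(t, 0, None), tau, plateau, i0), 100.0)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, n_frames)
    return frap.RecoveryTrace(t, y)


class TestExtractTrace:
    def test_matches_generating_closed_form(self, frap_setup):
        meta, droplet, bleach, bg = frap_setup
        truth = sd.FrapTruth(1.841, 66.18, 20.0, bleach_frame=5, bleach_roi=bleach)
        stack, _ = sd.simulate_frap_series(meta, droplet, truth, 60)
        trace = frap.extract_recovery_trace(stack, bleach, 5, bg, region="inside")
        t_post, y_post = trace.post_bleach
        expected = frap.exponential_recovery(t_post, 1.841, 66.18, 20.0)
        assert np.max(np.abs(y_post - expected) / expected) < 1e-3

    def test_pre_bleach_is_hundred(self, frap_setup):
        meta, droplet, bleach, bg = frap_setup
        truth = sd.FrapTruth(1.0, 70.0, 30.0, bleach_frame=10, bleach_roi=bleach)
        stack, _ = sd.simulate_frap_series(meta, droplet, truth, 20)
        trace = frap.extract_recovery_trace(stack, bleach, 10, bg)
        np.testing.assert_allclose(trace.intensity_pct[:10], 100.0, rtol=1e-9)

    def test_overlapping_background_rejected(self, frap_setup):
        meta, droplet, bleach, _ = frap_setup
        overlapping = CircleRoi((31.5, 31.5), 3.0)
        truth = sd.FrapTruth(1.0, 70.0, 30.0, bleach_frame=5, bleach_roi=bleach)
        stack, _ = sd.simulate_frap_series(meta, droplet, truth, 15)
        with pytest.raises(GeometryError, match="overlap"):
            frap.extract_recovery_trace(stack, bleach, 5, overlapping)

    def test_zero_signal_normalization_error(self, meta64):
        stack = TimelapseStack(np.full((10, 1, 64, 64), 20.0), meta64)
        roi = CircleRoi((31.5, 31.5), 1.5)
        bg = CircleRoi((8.0, 8.0), 0.6)
        with pytest.raises(NormalizationError):
            frap.extract_recovery_trace(stack, roi, 5, bg)

    def test_outside_region_follows_its_own_parameters(self, frap_setup):
        meta, droplet, bleach, bg = frap_setup
        inside = sd.FrapTruth(1.841, 66.18, 20.0, bleach_frame=5, bleach_roi=bleach)
        outside = sd.FrapTruth(1.905, 79.91, 40.0, bleach_frame=5, bleach_roi=bleach)
        stack, _ = sd.simulate_frap_series(meta, droplet, inside, 60, outside_truth=outside)
        trace = frap.extract_recovery_trace(stack, bleach, 5, bg, region="outside")
        fit = frap.fit_recovery(trace)
        assert fit.tau_s == pytest.approx(1.905, rel=1e-6)
        assert fit.plateau_pct == pytest.approx(79.91, rel=1e-6)


class TestFitRecovery:
    def test_exact_round_trip_on_noiseless_trace(self):
        fit = frap.fit_recovery(make_trace(1.841, 66.18, 20.0))
        assert fit.tau_s == pytest.approx(1.841, rel=1e-6)
        assert fit.plateau_pct == pytest.approx(66.18, rel=1e-6)
        assert fit.i0_pct == pytest.approx(20.0, rel=1e-6)
        assert fit.rss < 1e-12

    def test_constant_trace_unidentifiable(self):
        t = np.arange(-5, 20) * 0.2
        trace = frap.RecoveryTrace(t, np.full_like(t, 66.18))
        with pytest.raises(FitError, match="recover"):
            frap.fit_recovery(trace)

    def test_decreasing_trace_rejected(self):
        t = np.arange(-2, 20) * 0.2
        y = np.where(t >= 0, 80.0 - 2.0 * t, 100.0)
        with pytest.raises(FitError):
            frap.fit_recovery(frap.RecoveryTrace(t, y))

    def test_too_few_post_bleach_points(self):
        trace = frap.RecoveryTrace([-0.2, 0.0, 0.2], [100.0, 20.0, 30.0])
        with pytest.raises(FitError, match="3 post-bleach"):
            frap.fit_recovery(trace)

    def test_monte_carlo_calibration(self):
        """Mean fitted tau within 5% and plateau within 2 points at sigma=2."""
        taus, plateaus = [], []
        for seed in range(100):
            trace = make_trace(2.0, 66.18, 20.0, noise=2.0, seed=seed)
            fit = frap.fit_recovery(trace)
            taus.append(fit.tau_s)
            plateaus.append(fit.plateau_pct)
        assert abs(np.mean(taus) - 2.0) / 2.0 < 0.05
        assert abs(np.mean(plateaus) - 66.18) < 2.0


class TestEstimateDiffusion:
    def test_paper_style_magnitude(self):
        fit = frap.FrapFit(1.8, 66.0, 20.0, 0.0, 50)
        assert frap.estimate_diffusion(fit, 3.0) == pytest.approx(5.0)

    def test_identity_case(self):
        assert frap.estimate_diffusion(1.0, 1.0) == 1.0

    def test_quadratic_in_diameter(self):
        assert frap.estimate_diffusion(2.0, 4.0) == 4 * frap.estimate_diffusion(2.0, 2.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            frap.estimate_diffusion(1.0, 0.0)
        with pytest.raises(ValueError):
            frap.estimate_diffusion(-1.0, 2.0)


class TestKymograph:
    def test_row_count_is_steps_plus_one(self, meta64):
        stack = TimelapseStack(np.ones((4, 1, 64, 64)), meta64)
        line = LineRoi((5.0, 10.0), (35.0, 10.0))  # 30 steps
        assert frap.compute_kymograph(stack, line).n_positions == 31

    def test_constant_image_gives_constant_matrix(self, meta64):
        stack = TimelapseStack(np.full((3, 1, 64, 64), 42.0), meta64)
        kymo = frap.compute_kymograph(stack, LineRoi((2.0, 2.0), (60.0, 50.0), width_px=3))
        np.testing.assert_allclose(kymo.data, 42.0)

    def test_line_outside_frame_names_endpoint(self, meta64):
        stack = TimelapseStack(np.ones((1, 1, 64, 64)), meta64)
        with pytest.raises(GeometryError, match="p1"):
            frap.compute_kymograph(stack, LineRoi((5.0, 5.0), (80.0, 5.0)))

    def test_bleach_span_rises_toward_plateau(self, frap_setup):
        meta, droplet, bleach, _bg = frap_setup
        truth = sd.FrapTruth(0.8, 70.0, 15.0, bleach_frame=4, bleach_roi=bleach)
        stack, _ = sd.simulate_frap_series(meta, droplet, truth, 40, background=20.0)
        line = LineRoi((16.0, 31.5), (47.0, 31.5))
        kymo = frap.compute_kymograph(stack, line)
        # rows crossing the bleach ROI: |x - 31.5| <= 7.5 px along the line
        rows = slice(9, 23)
        span_means = kymo.data[rows].mean(axis=0)
        assert span_means[4] < span_means[10] < span_means[-1]

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        x0=st.floats(0, 63), y0=st.floats(0, 63),
        x1=st.floats(0, 63), y1=st.floats(0, 63),
    )
    def test_row_count_law_for_arbitrary_lines(self, x0, y0, x1, y1):
        if (x0, y0) == (x1, y1):
            return
        from condensate.io_formats import ImagingMeta

        meta = ImagingMeta(pixel_size_um=0.1, frame_interval_s=0.2)
        stack = TimelapseStack(np.ones((1, 1, 64, 64)), meta)
        line = LineRoi((x0, y0), (x1, y1))
        kymo = frap.compute_kymograph(stack, line)
        assert kymo.n_positions == int(np.floor(line.length_px)) + 1


class TestNormalizationInvariance:
    def test_rescaled_stack_same_trace_and_fit(self, frap_setup):
        meta, droplet, bleach, bg = frap_setup
        truth = sd.FrapTruth(1.5, 75.0, 25.0, bleach_frame=5, bleach_roi=bleach)
        stack, _ = sd.simulate_frap_series(meta, droplet, truth, 40, background=0.0)
        scaled = TimelapseStack(stack.data * 3.7, meta)
        t1 = frap.extract_recovery_trace(stack, bleach, 5, bg)
        t2 = frap.extract_recovery_trace(scaled, bleach, 5, bg)
        np.testing.assert_allclose(t1.intensity_pct, t2.intensity_pct, rtol=1e-9)
        f1, f2 = frap.fit_recovery(t1), frap.fit_recovery(t2)
        assert f1.tau_s == pytest.approx(f2.tau_s, rel=1e-8)
        assert f1.plateau_pct == pytest.approx(f2.plateau_pct, rel=1e-8)
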