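"""Ring fitting: peak detection, outlier rule, circle fit, fallback, full fit."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stedring import (
    BoundsError,
    DegenerateGeometryError,
    FitConfig,
    ImagePlane,
    NoSignalError,
    PolarPeakSet,
    detect_peak_points,
    exclude_outlier_peaks,
    fit_circle_lsq,
    fit_ring,
    segment_fallback,
)

from conftest import blurred_ring_image


def make_peaks(radii, retained=None):
    radii = np.asarray(radii, dtype=float)
    k = len(radii)
    return PolarPeakSet(
        center_used=(0.0, 0.0),
        angles=np.linspace(0, 2 * math.pi, k, endpoint=False),
        peak_radius_px=radii,
        peak_intensity=np.full(k, 100.0),
        retained=np.ones(k, bool) if retained is None else np.asarray(retained, bool),
    )


class TestDetectPeakPoints:
    def test_ideal_thin_ring_peaks_at_true_radius(self, uniform_ring_plane):
        peaks = detect_peak_points(uniform_ring_plane, (50.0, 50.0), FitConfig(r_max_px=20))
        assert peaks.retained.any()
        assert np.all(np.abs(peaks.peak_radius_px[peaks.retained] - 10.0) <= 0.5)

    def test_offset_seed_spreads_peak_radii(self, uniform_ring_plane):
        peaks = detect_peak_points(uniform_ring_plane, (52.0, 50.0), FitConfig(r_max_px=20))
        r = peaks.peak_radius_px[peaks.retained]
        assert r.min() < 8.6 and r.max() > 11.4
        assert np.all((r > 7.3) & (r < 12.7))

    def test_blurred_ring_matches_dense_1d_oracle(self):
        # oracle: brute-force maximization, on a 0.01-px grid, of the same
        # bilinear-interpolated radial profile the detector scans per ray
        from scipy.ndimage import map_coordinates

        sigma, radius = 2.0, 10.0
        img = ImagePlane(blurred_ring_image(sigma=sigma, radius=radius), 20.0)
        cfg = FitConfig(r_max_px=18)
        peaks = detect_peak_points(img, (50.0, 50.0), cfg)

        from scipy.special import i0e

        rho = np.arange(cfg.r_min_px, cfg.r_max_px, 0.01)
        for k in range(0, 360, 7):
            th = peaks.angles[k]
            rows = 50.0 + rho * np.cos(th)
            cols = 50.0 + rho * np.sin(th)
            dense = map_coordinates(img.pixels, np.vstack([rows, cols]), order=1)
            rho_star = rho[np.argmax(dense)]
            # per-ray agreement is limited by the kinks of the piecewise-
            # linear interpolated profile (raster pixel locking, ~0.25 px)
            assert abs(peaks.peak_radius_px[k] - rho_star) <= 0.25

        # the aggregate crest estimate — what the circle fit consumes — must
        # match the analytic optimum of the continuous blurred profile, which
        # sits inward of the true radius by the curvature shift
        prof_c = np.exp(-((rho - radius) ** 2) / (2 * sigma**2)) * i0e(rho * radius / sigma**2)
        rho_analytic = rho[np.argmax(prof_c)]
        med = np.median(peaks.peak_radius_px[peaks.retained])
        assert abs(med - rho_analytic) <= 0.05
        assert rho_analytic < radius  # inward crest shift of a curved ring

    def test_center_too_close_to_border_raises(self, uniform_ring_plane):
        with pytest.raises(BoundsError):
            detect_peak_points(uniform_ring_plane, (5.0, 50.0), FitConfig(r_max_px=20))

    def test_flat_image_raises_no_signal(self):
        img = ImagePlane(np.ones((101, 101)), 20.0)
        with pytest.raises(NoSignalError):
            detect_peak_points(img, (50.0, 50.0), FitConfig(r_max_px=20))


class TestOutlierExclusion:
    @pytest.mark.parametrize(
        "radii, expected_kept",
        [
            ([10, 10, 10, 10, 11.5], [True, True, True, True, False]),
            ([10, 10, 10, 10, 10], [True] * 5),
            # single-pass semantics: mean 10.6 excludes both 13 (22.6%) and
            # 9.5 (10.4%); the mean is NOT recomputed after dropping 13
            ([10.5, 9.5, 10, 10, 13], [True, False, True, True, False]),
        ],
    )
    def test_hand_computed_lists(self, radii, expected_kept):
        out = exclude_outlier_peaks(make_peaks(radii), 0.10)
        assert out.retained.tolist() == expected_kept

    def test_input_unmodified(self):
        peaks = make_peaks([10, 10, 10, 10, 11.5])
        exclude_outlier_peaks(peaks, 0.10)
        assert peaks.retained.all()

    def test_single_pass_rule_on_own_output(self):
        # after exclusion the surviving radii are all within the rule at
        # their new mean, so a second application changes nothing
        out = exclude_outlier_peaks(make_peaks([10, 10, 10, 10, 11.5]), 0.10)
        again = exclude_outlier_peaks(out, 0.10)
        assert (again.retained == out.retained).all()


class TestCircleFit:
    def test_exact_circle_recovered_to_1e9(self):
        th = np.linspace(0, 2 * math.pi, 36, endpoint=False)
        pts = np.column_stack([50 + 7 * np.cos(th), 50 + 7 * np.sin(th)])
        (cr, cc), r = fit_circle_lsq(pts)
        assert abs(cr - 50) < 1e-9 and abs(cc - 50) < 1e-9 and abs(r - 7) < 1e-9

    def test_analytic_circumcircle(self):
        (cr, cc), r = fit_circle_lsq(np.array([[0, 0], [2, 0], [1, 1]]))
        assert (cr, cc) == pytest.approx((1.0, 0.0), abs=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_circle_lsq(np.array([[0, 0], [1, 1], [2, 2]]))

    def test_too_few_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_circle_lsq(np.array([[0, 0], [1, 0]]))


class TestSegmentFallback:
    def test_gaussian_spot_radius_is_half_fwhm(self):
        rr, cc = np.meshgrid(np.arange(61), np.arange(61), indexing="ij")
        spot = 100 * np.exp(-((rr - 30) ** 2 + (cc - 30) ** 2) / (2 * 2.0**2))
        img = ImagePlane(spot, 20.0)
        res = segment_fallback(img, (30.0, 30.0), FitConfig(fallback_threshold_mode="fraction_of_max"))
        assert res.method == "segmentation_fallback"
        assert res.radius_px == pytest.approx(2.355, abs=0.5)

    def test_perfect_disk(self):
        rr, cc = np.meshgrid(np.arange(61), np.arange(61), indexing="ij")
        disk = 100.0 * (np.hypot(rr - 30, cc - 30) <= 5)
        res = segment_fallback(ImagePlane(disk, 20.0), (30.0, 30.0), FitConfig())
        assert res.center == pytest.approx((30.0, 30.0), abs=0.2)
        assert res.radius_px == pytest.approx(5.0, abs=0.5)

    def test_empty_window_raises(self):
        with pytest.raises(NoSignalError):
            segment_fallback(ImagePlane(np.zeros((61, 61)), 20.0), (30.0, 30.0), FitConfig())


class TestFitRing:
    def test_rendered_ring_recovered_despite_seed_jitter(self, single_ring_scene):
        truth, sted, _conf, centers = single_ring_scene
        c = centers.iloc[0]
        fit = fit_ring(sted, (c["row_px"], c["col_px"]), FitConfig())
        r_true_px = truth.rings[0].radius_nm / truth.params.pixel_size_nm
        assert fit.method == "radial_peak"
        assert abs(fit.radius_px - r_true_px) <= 0.25

    def test_filled_spot_routes_to_fallback(self):
        rr, cc = np.meshgrid(np.arange(101), np.arange(101), indexing="ij")
        spot = 100 * np.exp(-((rr - 50) ** 2 + (cc - 50) ** 2) / (2 * 3.0**2))
        fit = fit_ring(ImagePlane(spot, 20.0), (50.0, 50.0), FitConfig())
        assert fit.method == "segmentation_fallback"

    def test_background_seed_raises_no_signal(self):
        img = ImagePlane(np.zeros((101, 101)), 20.0)
        with pytest.raises(NoSignalError):
            fit_ring(img, (50.0, 50.0), FitConfig())

    def test_circumference_radius_ratio_is_2pi(self, single_ring_scene):
        _truth, sted, _conf, centers = single_ring_scene
        c = centers.iloc[0]
        fit = fit_ring(sted, (c["row_px"], c["col_px"]), FitConfig())
        assert fit.circumference_nm / fit.radius_nm == pytest.approx(2 * math.pi, rel=1e-12)

    def test_rotation_equivariance(self, single_ring_scene):
        _truth, sted, _conf, centers = single_ring_scene
        c = (centers.iloc[0]["row_px"], centers.iloc[0]["col_px"])
        fit0 = fit_ring(sted, c, FitConfig())
        rot = ImagePlane(np.ascontiguousarray(np.rot90(sted.pixels)), sted.pixel_size_nm)
        n = sted.pixels.shape[1]
        seed_rot = (n - 1 - c[1], c[0])  # rot90: (r, c) -> (ncol-1-c, r)
        fit1 = fit_ring(rot, seed_rot, FitConfig())
        assert abs(fit1.radius_px - fit0.radius_px) <= 0.1
        assert fit1.center[0] == pytest.approx(n - 1 - fit0.center[1], abs=0.2)
        assert fit1.center[1] == pytest.approx(fit0.center[0], abs=0.2)


@given(
    st.lists(st.floats(min_value=5.0, max_value=15.0), min_size=3, max_size=40),
    st.floats(min_value=0.05, max_value=0.5),
)
def test_outlier_rule_property(radii, frac):
    """Survivors always satisfy the rule at the pre-exclusion mean."""
    peaks = make_peaks(radii)
    out = exclude_outlier_peaks(peaks, frac)
    m = np.mean(radii)
    kept = out.peak_radius_px[out.retained]
    assert np.all(np.abs(kept - m) / m <= frac + 1e-12)
    dropped = out.peak_radius_px[~out.retained]
    assert np.all(np.abs(dropped - m) / m > frac - 1e-12)
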