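"""Synthetic scene generator: determinism, planted structure, rendering, labels."""

import dataclasses
import math

import numpy as np
import pytest

from stedring import (
    BoundsError,
    PlacementError,
    SceneConfig,
    SceneGroundTruth,
    TrueRing,
    ValidationError,
    expected_labels,
    generate_scene,
    render_scene,
)


def small_cfg(**kw):
    base = dict(
        image_size_px=(256, 256), n_cells=2, rings_per_cell_range=(1, 2),
        radius_range_nm=(120.0, 240.0), rng_seed=5,
    )
    base.update(kw)
    return SceneConfig(**base)


def two_tangentish_ring_truth(gap_px=0.0):
    """Two r=10 px rings with centers 20 px apart at 20 nm pixels."""
    cfg = small_cfg()
    rings = [
        TrueRing(0, (100.0, 100.0), 200.0),
        TrueRing(0, (100.0, 120.0 + gap_px), 200.0),
    ]
    k = 360
    return SceneGroundTruth(
        rings=rings,
        angular_truth_ch1=np.ones((2, k)),
        angular_truth_ch2=np.ones((2, k)),
        labels_between=np.zeros((2, k), bool),
        params=cfg,
    )


class TestGenerateScene:
    def test_same_seed_is_bit_identical(self):
        a = generate_scene(small_cfg())
        b = generate_scene(small_cfg())
        assert [r.center_px for r in a.rings] == [r.center_px for r in b.rings]
        np.testing.assert_array_equal(a.angular_truth_ch1, b.angular_truth_ch1)
        np.testing.assert_array_equal(a.angular_truth_ch2, b.angular_truth_ch2)
        np.testing.assert_array_equal(a.labels_between, b.labels_between)

    def test_full_coupling_makes_truths_proportional(self):
        t = generate_scene(small_cfg(coupling_alpha=1.0))
        for x, y in zip(t.angular_truth_ch1, t.angular_truth_ch2):
            assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_coupling_truths_uncorrelated_in_mean(self):
        # Monte-Carlo oracle: mean truth-vector correlation over >= 200
        # independent rings should vanish
        rs = []
        seed = 0
        while len(rs) < 200:
            cfg = small_cfg(coupling_alpha=0.0, n_cells=4, rings_per_cell_range=(2, 2),
                            image_size_px=(400, 400), rng_seed=seed)
            t = generate_scene(cfg)
            rs.extend(
                np.corrcoef(x, y)[0, 1]
                for x, y in zip(t.angular_truth_ch1, t.angular_truth_ch2)
            )
            seed += 1
        assert abs(np.mean(rs)) <= 0.05

    def test_label_conservation_and_cell_membership(self):
        t = generate_scene(small_cfg(n_cells=3, rings_per_cell_range=(2, 3),
                                     image_size_px=(512, 512)))
        assert t.labels_between.shape == (len(t.rings), 360)
        assert all(0 <= r.cell_id < 3 for r in t.rings)
        assert np.all(t.angular_truth_ch1 >= 0) and np.all(t.angular_truth_ch2 >= 0)

    def test_clustered_rings_are_tangent_within_one_pixel(self):
        t = generate_scene(small_cfg(n_cells=1, rings_per_cell_range=(3, 3),
                                     cluster_probability=1.0, image_size_px=(400, 400)))
        px = t.params.pixel_size_nm
        gaps = []
        for i, a in enumerate(t.rings):
            for b in t.rings[i + 1:]:
                d = math.hypot(a.center_px[0] - b.center_px[0],
                               a.center_px[1] - b.center_px[1])
                gaps.append(d - (a.radius_nm + b.radius_nm) / px)
        assert min(abs(g) for g in gaps) <= 1.0  # at least one tangency per cluster

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            generate_scene(small_cfg(image_size_px=(300, 300), n_cells=60))

    def test_degenerate_ranges_raise(self):
        with pytest.raises(ValidationError):
            small_cfg(radius_range_nm=(240.0, 120.0))
        with pytest.raises(ValidationError):
            small_cfg(psf_fwhm_conf_nm=50.0)
        with pytest.raises(ValidationError):
            small_cfg(radius_range_nm=(30.0, 240.0))  # < 2 px

    def test_truth_json_roundtrip(self):
        t = generate_scene(small_cfg())
        t2 = SceneGroundTruth.from_json(t.to_json())
        np.testing.assert_allclose(t2.angular_truth_ch1, t.angular_truth_ch1)
        np.testing.assert_array_equal(t2.labels_between, t.labels_between)
        assert t2.params == t.params


class TestRenderScene:
    def test_determinism_including_noise(self):
        t = generate_scene(small_cfg())
        s1, c1, cen1 = render_scene(t, noise=True)
        s2, c2, cen2 = render_scene(t, noise=True)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        np.testing.assert_array_equal(c1.pixels, c2.pixels)
        assert cen1.equals(cen2)

    def test_crest_on_circle_for_uniform_ring(self):
        t = two_tangentish_ring_truth()
        t = dataclasses.replace(t, rings=[t.rings[0]],
                                angular_truth_ch1=t.angular_truth_ch1[:1],
                                angular_truth_ch2=t.angular_truth_ch2[:1],
                                labels_between=t.labels_between[:1])
        sted, _conf, _ = render_scene(t, noise=False)
        peak = np.unravel_index(np.argmax(sted.pixels), sted.pixels.shape)
        d = math.hypot(peak[0] - 100.0, peak[1] - 100.0)
        assert abs(d - 10.0) <= 0.5 + 1e-9

    def test_foreground_linear_in_photon_budget(self):
        t = generate_scene(small_cfg())
        s1, _c1, _ = render_scene(t, noise=False)
        t2 = dataclasses.replace(
            t, params=dataclasses.replace(t.params, photon_budget=2 * t.params.photon_budget)
        )
        s2, _c2, _ = render_scene(t2, noise=False)
        bg = t.params.background_level
        np.testing.assert_allclose(s2.pixels - bg, 2.0 * (s1.pixels - bg),
                                   rtol=1e-7, atol=1e-12)

    def test_center_jitter_at_most_two_pixels(self):
        t = generate_scene(small_cfg())
        _s, _c, centers = render_scene(t, noise=False)
        for _, row in centers.iterrows():
            ring = t.rings[int(row["ring_id"])]
            assert abs(row["row_px"] - ring.center_px[0]) <= 2.0
            assert abs(row["col_px"] - ring.center_px[1]) <= 2.0

    def test_out_of_bounds_ring_raises_naming_it(self):
        t = two_tangentish_ring_truth()
        bad = dataclasses.replace(t, rings=[TrueRing(0, (3.0, 100.0), 200.0), t.rings[1]])
        with pytest.raises(BoundsError, match="3.0"):
            render_scene(bad, noise=False)


class TestExpectedLabels:
    def test_isolated_ring_all_outside(self):
        t = two_tangentish_ring_truth()
        t = dataclasses.replace(t, rings=[t.rings[0]],
                                angular_truth_ch1=t.angular_truth_ch1[:1],
                                angular_truth_ch2=t.angular_truth_ch2[:1],
                                labels_between=t.labels_between[:1])
        assert not expected_labels(t, 30.0).any()

    def test_analytic_tangent_pair_between_fraction(self):
        # r = 10 px, centers 20 px apart, 20 nm pixels, 30 nm gap:
        # Between iff |sqrt(500 - 400 cos t) - 10| <= 1.5 px, i.e.
        # cos t >= 0.91936 -> 47 of 360 one-degree samples (12.9% +/- 1 sample)
        t = two_tangentish_ring_truth()
        lab = expected_labels(t, 30.0)
        for i in range(2):
            frac = lab[i].mean()
            assert abs(frac - 0.12874) <= 1.0 / 360 + 1e-9

    def test_infinite_gap_labels_everything_between(self):
        t = two_tangentish_ring_truth()
        assert expected_labels(t, 1e12).all()

    def test_nonpositive_gap_raises(self):
        t = two_tangentish_ring_truth()
        with pytest.raises(ValidationError):
            expected_labels(t, 0.0)
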