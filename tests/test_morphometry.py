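"""Profile-AUC densities and keel geometry against analytic oracles."""

import numpy as np
import pytest

from keelmorph.morphometry import (IntensityProfile, background_correct,
                                   keel_density, keel_geometry,
                                   keel_spline_length, measure_image,
                                   profile_auc, profile_curve,
                                   tibiotarsal_density)
from keelmorph.radiograph_io import KeypointAnnotation, Radiograph
from keelmorph.synthetic_data import PhantomSpec, make_phantom

from conftest import flat_image, rotate90


def dense_profile_oracle(image, start, end, width_px, step_px=1.0,
                         perp_step=0.1):
    """Brute-force wide-line profile: 0.1-px perpendicular sampling."""
    from scipy.ndimage import map_coordinates

    p0, p1 = np.asarray(start, float), np.asarray(end, float)
    length = np.hypot(*(p1 - p0))
    u = (p1 - p0) / length
    v = np.array([-u[1], u[0]])
    n_pos = max(2, int(round(length / step_px)) + 1)
    t = np.linspace(0, length, n_pos)
    offs = np.arange(-(width_px - 1) / 2, (width_px - 1) / 2 + 1e-9, perp_step)
    vals = []
    for ti in t:
        pts = p0 + ti * u + offs[:, None] * v
        s = map_coordinates(image.pixels, [pts[:, 1], pts[:, 0]], order=1,
                            mode="nearest")
        vals.append(s.mean())
    return t, np.array(vals)


class TestProfileCurve:
    def test_constant_field(self):
        img = flat_image(7.0)
        prof = profile_curve(img, (10, 30), (60, 90), width_px=5)
        np.testing.assert_allclose(prof.values, 7.0)

    def test_linear_ramp_is_its_own_profile(self):
        px = np.tile(np.arange(128, dtype=float), (128, 1))  # I(x,y) = x
        img = Radiograph(pixels=px, photometric_normalized=True)
        prof = profile_curve(img, (10, 50), (20, 50), width_px=3)
        np.testing.assert_allclose(prof.values, 10 + prof.positions,
                                   atol=1e-6)

    def test_random_texture_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        img = Radiograph(pixels=rng.random((128, 128)) * 100,
                         photometric_normalized=True)
        start, end = (20.3, 40.7), (90.1, 70.2)
        prof = profile_curve(img, start, end, width_px=9)
        t, vals = dense_profile_oracle(img, start, end, width_px=9)
        np.testing.assert_allclose(prof.positions, t)
        assert np.max(np.abs(prof.values - vals)) < 1e-3 * 100

    def test_region_overflow_names_side(self):
        img = flat_image()
        with pytest.raises(ValueError, match="right"):
            profile_curve(img, (120, 60), (140, 60), width_px=3)
        with pytest.raises(ValueError, match="top"):
            profile_curve(img, (30, 2), (60, 2), width_px=9)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            profile_curve(flat_image(), (10, 10), (10, 10), width_px=3)


class TestProfileAuc:
    def test_rectangle(self):
        prof = IntensityProfile(np.arange(0, 11.0), np.full(11, 3.0), 1.0)
        assert profile_auc(prof) == pytest.approx(3.0 * 10.0)

    def test_trapezoid_arithmetic(self):
        prof = IntensityProfile(np.array([0.0, 1.0, 2.0]),
                                np.array([1.0, 2.0, 3.0]), 1.0)
        assert profile_auc(prof) == pytest.approx(4.0)

    def test_linearity_in_values(self):
        rng = np.random.default_rng(0)
        v = rng.random(20)
        p = np.arange(20.0)
        a1 = profile_auc(IntensityProfile(p, v, 1.0))
        a2 = profile_auc(IntensityProfile(p, 2 * v, 1.0))
        assert a2 == pytest.approx(2 * a1, rel=1e-12)


class TestTibiotarsalDensity:
    def _band_image(self, level=50.0, x0=100, x1=200):
        px = np.zeros((400, 400))
        px[:, x0:x1 + 1] = level
        return Radiograph(pixels=px, photometric_normalized=True)

    def test_uniform_band_closed_form(self):
        img = self._band_image()
        ann = KeypointAnnotation(
            image_id="t", tibiotarsal_line=[[110, 200], [190, 200]])
        auc, _ = tibiotarsal_density(img, ann, correct_background=False)
        assert auc == pytest.approx(50.0 * 80.0, rel=0.005)

    def test_scales_with_drawn_bone_width(self):
        img = self._band_image(x0=50, x1=350)
        short = KeypointAnnotation(
            image_id="s", tibiotarsal_line=[[100, 200], [180, 200]])
        long = KeypointAnnotation(
            image_id="l", tibiotarsal_line=[[100, 200], [260, 200]])
        a1, _ = tibiotarsal_density(img, short, correct_background=False)
        a2, _ = tibiotarsal_density(img, long, correct_background=False)
        assert a2 == pytest.approx(2 * a1, rel=1e-6)

    def test_width_normalized_variant(self):
        img = self._band_image()
        ann = KeypointAnnotation(
            image_id="t", tibiotarsal_line=[[110, 200], [190, 200]])
        d, _ = tibiotarsal_density(img, ann, correct_background=False,
                                   width_normalized=True)
        assert d == pytest.approx(50.0, rel=0.005)

    def test_gaussian_cross_section_matches_oracle(self):
        yy, xx = np.mgrid[0:300, 0:300].astype(float)
        px = 80.0 * np.exp(-((xx - 150) / 25.0) ** 2)
        img = Radiograph(pixels=px, photometric_normalized=True)
        ann = KeypointAnnotation(
            image_id="g", tibiotarsal_line=[[100, 150], [200, 150]])
        auc, _ = tibiotarsal_density(img, ann, correct_background=False)
        t, vals = dense_profile_oracle(img, (100, 150), (200, 150), 100)
        oracle = np.trapezoid(vals, t)
        assert auc == pytest.approx(oracle, rel=1e-3)


class TestSplineLength:
    def test_straight_segment(self):
        length, mid = keel_spline_length([(0, 0), (3, 4)])
        assert length == pytest.approx(5.0)
        assert mid == pytest.approx((1.5, 2.0))

    def test_collinear_points(self):
        pts = [(0, 0), (2, 0), (5, 0), (7, 0), (10, 0)]
        length, mid = keel_spline_length(pts)
        assert length == pytest.approx(10.0, abs=1e-6)
        assert mid == pytest.approx((5.0, 0.0), abs=1e-6)

    def test_quarter_circle_arc_length(self):
        theta = np.linspace(0, np.pi / 2, 9)
        pts = [(100 * np.cos(t), 100 * np.sin(t)) for t in theta]
        length, _ = keel_spline_length(pts)
        assert length == pytest.approx(100 * np.pi / 2, rel=0.01)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError):
            keel_spline_length([(0, 0), (0, 0), (1, 1)])


class TestKeelGeometry:
    def test_worked_example_undamaged_keel(self):
        # an undamaged keel: length 10 cm, mid-depth 2 cm -> ratio 5
        img = flat_image(shape=(600, 600))
        mm_per_cm = 10.0
        ann = KeypointAnnotation(
            image_id="w",
            keel_polyline=[(50, 300), (50 + 10 * mm_per_cm, 300)],
            middepth_line=[(100, 290), (100, 290 + 2 * mm_per_cm)],
            cranialdepth_line=[(60, 280), (60, 310)],
        )
        length, mid, _, xlm = keel_geometry(img, ann)
        assert length == pytest.approx(100.0)
        assert mid == pytest.approx(20.0)
        assert xlm == pytest.approx(5.0)

    def test_length_equal_middepth_gives_unit_ratio(self):
        img = flat_image(shape=(128, 128))
        ann = KeypointAnnotation(
            image_id="i",
            keel_polyline=[(10, 60), (40, 60)],
            middepth_line=[(25, 45), (25, 75)],
            cranialdepth_line=[(12, 50), (12, 70)],
        )
        *_, xlm = keel_geometry(img, ann)
        assert xlm == pytest.approx(1.0)

    def test_phantom_ground_truth_within_2pct(self, phantom_noisy):
        img, ann, truth = phantom_noisy
        length, mid, cran, xlm = keel_geometry(img, ann)
        assert length == pytest.approx(truth["keel_length_px"], rel=0.02)
        assert mid == pytest.approx(truth["mid_depth_px"], rel=0.02)
        assert cran == pytest.approx(truth["cranial_depth_px"], rel=0.02)
        assert xlm == pytest.approx(truth["xlm"], rel=0.02)

    def test_zero_middepth_is_error(self):
        img = flat_image()
        ann = KeypointAnnotation(image_id="z",
                                 keel_polyline=[(10, 60), (40, 60)],
                                 middepth_line=[(25, 45), (25, 45)],
                                 cranialdepth_line=[(12, 50), (12, 70)])
        with pytest.raises(ValueError, match="mid-depth"):
            keel_geometry(img, ann)


class TestKeelDensity:
    def test_uniform_block_closed_form(self, phantom_clean):
        img, ann, truth = phantom_clean
        auc, _ = keel_density(img, ann, correct_background=False)
        assert auc == pytest.approx(truth["keel_auc"], rel=0.005)

    def test_zero_image(self):
        img = flat_image(0.0, shape=(400, 400), mm_per_px=0.2)
        ann = KeypointAnnotation(
            image_id="z",
            keeldensity_anchor={"point": [200, 100], "direction": [0, 1]})
        auc, _ = keel_density(img, ann, correct_background=False)
        assert auc == pytest.approx(0.0, abs=1e-9)

    def test_missing_spacing_is_error(self):
        img = flat_image(1.0, shape=(400, 400))
        ann = KeypointAnnotation(
            image_id="m",
            keeldensity_anchor={"point": [200, 100], "direction": [0, 1]})
        with pytest.raises(ValueError, match="10 mm"):
            keel_density(img, ann)

    def test_fallback_spacing_used(self):
        img = flat_image(2.0, shape=(400, 400))
        ann = KeypointAnnotation(
            image_id="f",
            keeldensity_anchor={"point": [200, 100], "direction": [0, 1]})
        auc, _ = keel_density(img, ann, correct_background=False,
                              fallback_mm_per_px=0.2)
        assert auc == pytest.approx(2.0 * 10.0, rel=0.005)


class TestBackgroundCorrection:
    def test_arithmetic(self):
        img = flat_image(2.0)
        ann = KeypointAnnotation(image_id="b",
                                 background_region=[5, 5, 30, 30])
        corrected, level = background_correct(100.0, img, ann, 10.0)
        assert corrected == pytest.approx(80.0)
        assert level == pytest.approx(2.0)

    def test_zero_background_unchanged(self):
        img = flat_image(0.0)
        ann = KeypointAnnotation(image_id="b",
                                 background_region=[5, 5, 30, 30])
        corrected, _ = background_correct(100.0, img, ann, 10.0)
        assert corrected == pytest.approx(100.0)

    def test_absent_region_passes_through(self):
        img = flat_image(3.0)
        ann = KeypointAnnotation(image_id="b")
        corrected, level = background_correct(100.0, img, ann, 10.0)
        assert corrected == 100.0
        assert level is None

    def test_haze_invariance(self):
        base = make_phantom(PhantomSpec(seed=3, haze=0.0))
        hazy = make_phantom(PhantomSpec(seed=3, haze=20.0))
        d0, _ = keel_density(base[0], base[1])
        dh, _ = keel_density(hazy[0], hazy[1])
        assert dh == pytest.approx(d0, rel=0.01)


class TestMeasurementProperties:
    def test_rotation_equivariance(self, phantom_noisy):
        img, ann, _ = phantom_noisy
        rot, mp = rotate90(img)
        rann = KeypointAnnotation(
            image_id=ann.image_id,
            tibiotarsal_line=[mp(p) for p in ann.tibiotarsal_line],
            keel_polyline=[mp(p) for p in ann.keel_polyline],
            middepth_line=[mp(p) for p in ann.middepth_line],
            cranialdepth_line=[mp(p) for p in ann.cranialdepth_line],
            keeldensity_anchor={
                "point": mp(ann.keeldensity_anchor["point"]),
                "direction": (ann.keeldensity_anchor["direction"][1],
                              -ann.keeldensity_anchor["direction"][0]),
            },
        )
        r0 = measure_image(img, ann, correct_background=False)
        r1 = measure_image(rot, rann, correct_background=False)
        for f in ("tibiotarsal_density", "keel_density", "keel_length_px",
                  "keel_mid_depth_px", "xlm"):
            assert getattr(r1, f) == pytest.approx(getattr(r0, f), rel=0.005)

    def test_intensity_linearity(self, phantom_clean):
        img, ann, _ = phantom_clean
        scaled = Radiograph(pixels=3.0 * img.pixels, mm_per_px=img.mm_per_px,
                            photometric_normalized=True)
        d0, _ = tibiotarsal_density(img, ann, correct_background=False)
        d1, _ = tibiotarsal_density(scaled, ann, correct_background=False)
        assert d1 == pytest.approx(3.0 * d0, rel=1e-9)
        k0, _ = keel_density(img, ann, correct_background=False)
        k1, _ = keel_density(scaled, ann, correct_background=False)
        assert k1 == pytest.approx(3.0 * k0, rel=1e-9)

    def test_jittered_annotations_reproducible(self):
        """Re-measuring with 1 px keypoint jitter keeps test-retest
        correlation high across a phantom batch (operator repeatability)."""
        rng = np.random.default_rng(11)
        firsts, seconds = [], []
        for i in range(50):
            spec = PhantomSpec(seed=100 + i, noise_sd=1.0,
                               cranial_depth_px=25.0 + 10.0 * (i % 7))
            img, ann, _ = make_phantom(spec)

            def jitter(pts):
                return [(x + rng.normal(0, 1), y + rng.normal(0, 1))
                        for x, y in pts]

            jann = KeypointAnnotation(
                image_id=ann.image_id,
                cranialdepth_line=jitter(ann.cranialdepth_line))
            c0 = np.hypot(*np.subtract(*ann.cranialdepth_line))
            c1 = np.hypot(*np.subtract(*jann.cranialdepth_line))
            firsts.append(c0)
            seconds.append(c1)
        r = np.corrcoef(firsts, seconds)[0, 1]
        assert r >= 0.9
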