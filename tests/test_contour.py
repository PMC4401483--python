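"""Slit-band centreline, baseline, and height reconstruction."""

import math

import numpy as np
import pytest

from slitfundus import contour as ct
from slitfundus import synthetic as syn
from slitfundus.optics import FundusLens, ScaleCalibration


def _band_image(center_x=120.4, shape=(100, 256), amplitude=0.8, width=4.0,
                background=0.05, noise=0.0, rng=None):
    cols = np.arange(shape[1])
    profile = amplitude * np.exp(-0.5 * ((cols - center_x) / width) ** 2)
    img = background + np.tile(profile, (shape[0], 1))
    if noise and rng is not None:
        img = img + rng.normal(0, noise, img.shape)
    return np.clip(img, 0, 1)


def _obs(img, angle=5.0, side="left", mm_per_px=0.01, power=90.0):
    lens = FundusLens(power)
    cal = ScaleCalibration(1.0 / (mm_per_px * lens.mag_factor))
    return ct.SlitObservation(img, angle, side, cal, lens)


class TestCenterline:
    def test_subpixel_position(self):
        c = ct.detect_centerline(_obs(_band_image(120.4)))
        assert np.all(np.abs(c - 120.4) < 0.3)

    def test_uniform_image_raises(self):
        with pytest.raises(ct.BandDetectionError):
            ct.detect_centerline(_obs(np.full((50, 100), 0.4)))

    def test_two_bands_ambiguous_with_candidates(self):
        img = np.maximum(_band_image(60.0), _band_image(190.0))
        with pytest.raises(ct.BandAmbiguityError) as exc:
            ct.detect_centerline(_obs(img))
        assert len(exc.value.candidates_px) == 2

    def test_noise_robustness_monte_carlo(self):
        # additive noise at 5 % of band amplitude: mean centroid error stays
        # below half a pixel over 100 draws
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            img = _band_image(120.4, shape=(20, 256), noise=0.04, rng=rng)
            c = ct.detect_centerline(_obs(img))
            errs.append(np.nanmean(np.abs(c - 120.4)))
        assert np.mean(errs) <= 0.5


class TestBaseline:
    def test_straight_centerline_small_residuals(self):
        rows = np.arange(80, dtype=float)
        center = 100.0 + 0.05 * rows
        fit = ct.fit_baseline(center)
        assert np.max(np.abs(fit - center)) < 0.2

    def test_excluded_bump_matches_flanks(self):
        rows = np.arange(120, dtype=float)
        center = 90.0 + 0.02 * rows
        bumped = center.copy()
        bumped[50:70] += 8.0
        excl = np.zeros(120, bool)
        excl[50:70] = True
        fit = ct.fit_baseline(bumped, excl)
        assert np.max(np.abs(fit - center)) < 0.3

    def test_auto_exclusion_finds_bump(self):
        rows = np.arange(120, dtype=float)
        bumped = 90.0 + 0.02 * rows
        bumped[50:70] += 8.0
        mask = ct.auto_exclusion_mask(bumped)
        assert mask[55:65].all()
        assert not mask[:40].any()

    def test_insufficient_support_raises(self):
        with pytest.raises(ct.BaselineError):
            ct.fit_baseline(np.full(30, 10.0), np.ones(30, bool))


class TestHeightFromDeflection:
    def test_zero_deflection(self):
        assert ct.height_from_deflection(0.0, 5.0) == 0

    def test_tan45_unity(self):
        assert ct.height_from_deflection(1.0, 45.0) == pytest.approx(1.0)

    def test_macular_hole_depth_from_small_deflection(self):
        # 0.0481 mm deflection away from the arm at a 5 deg beam angle is a
        # 0.55 mm deep depression: -0.0481 / tan(5 deg) = -0.5498
        h = ct.height_from_deflection(-0.0481, 5.0)
        assert h == pytest.approx(-0.55, abs=0.005)

    @pytest.mark.parametrize("angle", [0.0, 90.0, -5.0, 120.0])
    def test_invalid_geometry(self, angle):
        with pytest.raises(ValueError):
            ct.height_from_deflection(1.0, angle)


class TestReconstruction:
    @pytest.mark.parametrize("angle", [5.0, 10.0, 15.0])
    @pytest.mark.parametrize("side", ["left", "right"])
    def test_pit_depth_recovered_within_5_percent(self, phantom256, angle, side):
        hm = syn.gaussian_pit(phantom256.green.shape, depth_mm=0.5)
        img = syn.render_slit(
            phantom256, hm, syn.SlitGeometry(angle_deg=angle, arm_side=side)
        )
        prof = ct.reconstruct_profile(_obs(img, angle, side, phantom256.mm_per_px))
        assert min(prof.height_mm) == pytest.approx(-0.5, rel=0.05)

    def test_flat_map_is_flat(self, phantom256):
        hm = syn.HeightMap(np.zeros(phantom256.green.shape))
        img = syn.render_slit(phantom256, hm, syn.SlitGeometry())
        prof = ct.reconstruct_profile(_obs(img, 5.0, "left", phantom256.mm_per_px))
        assert np.max(np.abs(prof.height_mm)) < 0.02

    def test_deflection_doubles_with_tan_ratio(self, phantom256):
        hm = syn.gaussian_pit(phantom256.green.shape, depth_mm=0.5)
        defl = {}
        for angle in (5.0, 10.0):
            img = syn.render_slit(
                phantom256, hm, syn.SlitGeometry(angle_deg=angle, arm_side="left")
            )
            obs = _obs(img, angle, "left", phantom256.mm_per_px)
            c = ct.detect_centerline(obs)
            b = ct.fit_baseline(c, ct.auto_exclusion_mask(c))
            defl[angle] = np.nanmax(np.abs(c - b))
        expected = math.tan(math.radians(10)) / math.tan(math.radians(5))
        assert defl[10.0] / defl[5.0] == pytest.approx(expected, rel=0.07)

    def test_bump_is_positive_pit_is_negative(self, phantom256):
        for maker, sign in ((syn.gaussian_bump, 1), (syn.gaussian_pit, -1)):
            hm = maker(phantom256.green.shape)
            img = syn.render_slit(phantom256, hm, syn.SlitGeometry(angle_deg=10))
            prof = ct.reconstruct_profile(_obs(img, 10.0, "left", phantom256.mm_per_px))
            peak = prof.height_mm[np.argmax(np.abs(prof.height_mm))]
            assert np.sign(peak) == sign

    def test_arm_swap_preserves_height_sign(self, phantom256):
        hm = syn.gaussian_pit(phantom256.green.shape, depth_mm=0.5)
        mins = []
        for side in ("left", "right"):
            img = syn.render_slit(
                phantom256, hm, syn.SlitGeometry(angle_deg=10, arm_side=side)
            )
            prof = ct.reconstruct_profile(_obs(img, 10.0, side, phantom256.mm_per_px))
            mins.append(min(prof.height_mm))
        assert mins[0] == pytest.approx(mins[1], rel=0.05)
        assert all(m < -0.4 for m in mins)

    def test_linearity_in_small_angle_regime(self, phantom256):
        depths = []
        for d in (0.3, 0.6):
            hm = syn.gaussian_pit(phantom256.green.shape, depth_mm=d)
            img = syn.render_slit(phantom256, hm, syn.SlitGeometry(angle_deg=10))
            prof = ct.reconstruct_profile(_obs(img, 10.0, "left", phantom256.mm_per_px))
            depths.append(-min(prof.height_mm))
        assert depths[1] / depths[0] == pytest.approx(2.0, rel=0.03)


class TestLesionMetrics:
    def test_pit_depth_and_flags(self, phantom256):
        hm = syn.gaussian_pit(phantom256.green.shape, depth_mm=0.5)
        img = syn.render_slit(phantom256, hm, syn.SlitGeometry(angle_deg=10))
        prof = ct.reconstruct_profile(_obs(img, 10.0, "left", phantom256.mm_per_px))
        m = ct.lesion_metrics(prof)
        assert not m["no_lesion"]
        assert m["depth_mm"] == pytest.approx(0.5, rel=0.05)
        assert m["extent_mm"] > 0

    def test_flat_profile(self):
        prof = ct.HeightProfile(np.arange(10.0), np.zeros(10), np.ones(10, bool))
        m = ct.lesion_metrics(prof)
        assert m == {"depth_mm": 0.0, "extent_mm": 0.0, "no_lesion": True}

    def test_two_disjoint_pits_span_outermost_crossings(self):
        pos = np.arange(200) * 0.01
        h = np.zeros(200)
        h[40:60] = -0.5
        h[140:160] = -0.3
        prof = ct.HeightProfile(pos, h, np.ones(200, bool))
        m = ct.lesion_metrics(prof)
        # brute-force oracle: scan every adjacent pair for threshold
        # crossings with linear interpolation, keep the outermost two
        thr = -0.1 * 0.5
        crossings = []
        for i in range(199):
            lo, hi_ = h[i], h[i + 1]
            if (lo >= thr) != (hi_ >= thr):
                t = (thr - lo) / (hi_ - lo)
                crossings.append(pos[i] + t * (pos[i + 1] - pos[i]))
        expected = max(crossings) - min(crossings)
        assert m["extent_mm"] == pytest.approx(expected, abs=1e-9)
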