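"""Ground-truth integrity of the synthetic fundus generators."""

import math

import numpy as np
import pytest

from slitfundus import synthetic as syn


class TestPhantom:
    def test_same_seed_bit_identical(self):
        a = syn.generate_phantom(1, size=(128, 128))
        b = syn.generate_phantom(1, size=(128, 128))
        assert np.array_equal(a.image, b.image)

    def test_different_seed_differs(self):
        a = syn.generate_phantom(1, size=(128, 128))
        b = syn.generate_phantom(2, size=(128, 128))
        assert not np.array_equal(a.image, b.image)

    def test_zero_vessel_density(self):
        p = syn.generate_phantom(1, size=(128, 128), vessel_density=0)
        assert not p.vessel_mask.any()
        assert len(p.vessel_points_px) == 0

    def test_green_vessel_contrast_at_least_twice_red(self, phantom256):
        p = phantom256
        v, bg = p.vessel_mask, ~p.vessel_mask
        green_c = p.image[..., 1][bg].mean() - p.image[..., 1][v].mean()
        red_c = p.image[..., 0][bg].mean() - p.image[..., 0][v].mean()
        assert green_c >= 2 * red_c > 0

    def test_disc_and_fovea_inside_frame(self, phantom256):
        h, w = phantom256.green.shape
        for r, c in (phantom256.disc_center_px, phantom256.fovea_px):
            assert 0 <= r < h and 0 <= c < w

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_phantom(1, size=(16, 16))
        with pytest.raises(ValueError):
            syn.generate_phantom(1, vessel_density=-1)


class TestHeightMaps:
    def test_zero_outside_lesion_support(self):
        hm = syn.gaussian_pit((128, 128), depth_mm=0.5, radius_mm=0.3)
        d = np.hypot(*np.mgrid[0:128, 0:128] - 64.0) * syn.DEFAULT_MM_PER_PX
        assert np.all(hm.height_mm[d > 0.6] == 0)

    def test_pit_bottom_and_bump_top(self):
        pit = syn.gaussian_pit((64, 64), depth_mm=0.4)
        bump = syn.gaussian_bump((64, 64), height_mm=0.4)
        assert pit.height_mm.min() == pytest.approx(-0.4, rel=1e-6)
        assert bump.height_mm.max() == pytest.approx(0.4, rel=1e-6)


def _band_centers(img, frac=0.6):
    """Per-row centroid of the bright band (independent few-line oracle)."""
    thr = frac * img.max()
    w = np.where(img > thr, img - thr, 0.0)
    cols = np.arange(img.shape[1])
    return (w * cols).sum(axis=1) / w.sum(axis=1)


class TestRenderSlit:
    def test_flat_map_straight_band(self, phantom256):
        img = syn.render_slit(
            phantom256, syn.HeightMap(np.zeros(phantom256.green.shape)),
            syn.SlitGeometry(),
        )
        assert np.ptp(_band_centers(img)) <= 1

    def test_pit_displacement_matches_tangent(self, phantom256):
        depth, angle = 0.5, 5.0
        hm = syn.gaussian_pit(phantom256.green.shape, depth_mm=depth)
        img = syn.render_slit(
            phantom256, hm, syn.SlitGeometry(angle_deg=angle, arm_side="left")
        )
        c = _band_centers(img)
        dx_px = c.max() - np.median(c)  # pit pushes the band away from a left arm
        expected_px = depth * math.tan(math.radians(angle)) / phantom256.mm_per_px
        assert dx_px == pytest.approx(expected_px, abs=1.0)

    def test_arm_mirror_flips_displacement(self, phantom256):
        hm = syn.gaussian_pit(phantom256.green.shape, depth_mm=0.5)
        geom = dict(width_mm=0.3, angle_deg=10.0)
        left = _band_centers(
            syn.render_slit(phantom256, hm, syn.SlitGeometry(arm_side="left", **geom))
        )
        right = _band_centers(
            syn.render_slit(phantom256, hm, syn.SlitGeometry(arm_side="right", **geom))
        )
        assert (left.max() - np.median(left)) == pytest.approx(
            -(right.min() - np.median(right)), abs=1.0
        )

    def test_background_dimmed(self, phantom256):
        img = syn.render_slit(
            phantom256, syn.HeightMap(np.zeros(phantom256.green.shape)),
            syn.SlitGeometry(),
        )
        band_col = phantom256.green.shape[1] // 2
        assert img[:, band_col].mean() > 4 * img[:, 20].mean()


class TestTiles:
    def test_grid3x3_yields_9_tiles_with_truth(self, phantom512):
        tiles = syn.make_tiles(phantom512, "grid3x3", tile_px=140)
        assert len(tiles) == 9
        assert {t.gaze_label for t in tiles} >= {"center", "up", "down-temporal"}
        for t in tiles:
            assert t.sidecar["offset_px"] == list(t.offset_px)

    def test_pair_overlap_nonempty_and_recorded(self, phantom512):
        a, b = syn.make_tiles(phantom512, "pair", overlap_deg=2.0, tile_px=160)
        assert a.sidecar["overlap_deg"] == b.sidecar["overlap_deg"] == 2.0
        assert abs(a.offset_px[1] - b.offset_px[1]) < 160

    def test_zero_overlap_adjacent(self, phantom512):
        tiles = syn.make_tiles(phantom512, "grid3x3", overlap_deg=0.0, tile_px=120)
        rows = sorted({t.offset_px[0] for t in tiles})
        assert rows[1] - rows[0] == 120

    def test_layout_exceeding_extent_errors(self, phantom256):
        with pytest.raises(ValueError):
            syn.make_tiles(phantom256, "grid3x3", tile_px=200)


class TestVideoAndChange:
    def test_video_deterministic(self, phantom256):
        a, _ = syn.make_video(phantom256, 5, seed=9)
        b, _ = syn.make_video(phantom256, 5, seed=9)
        assert np.array_equal(a, b)

    def test_blink_frames_near_black(self, phantom256):
        frames, truth = syn.make_video(phantom256, 6, blink_frames=(2,), seed=0)
        assert frames[2].mean() < 0.3 * frames[0].mean()
        assert truth["blink_indices"] == [2]

    def test_equal_blur_all_sharp(self, phantom256):
        _, truth = syn.make_video(phantom256, 5, seed=0)
        assert truth["sharp_indices"] == [0, 1, 2, 3, 4]

    def test_change_confined_to_mask(self, phantom256):
        d = syn.make_change_pair(phantom256, "vessel_shift", 2.0, seed=4)
        outside = ~d["change_mask"]
        assert np.array_equal(d["before"][outside], d["after"][outside])
        assert (d["before"][d["change_mask"]] != d["after"][d["change_mask"]]).any()

    def test_vessel_shift_truth_vectors(self, phantom256):
        d = syn.make_change_pair(phantom256, "vessel_shift", 2.0, seed=4)
        mags = np.hypot(d["displacements_px"][:, 0], d["displacements_px"][:, 1])
        assert np.allclose(mags, 2.0)

    def test_zero_magnitude_rejected(self, phantom256):
        with pytest.raises(ValueError):
            syn.make_change_pair(phantom256, "vessel_shift", 0.0)

    @pytest.mark.parametrize("kind", ["atrophy_growth", "hemorrhage"])
    def test_other_change_types(self, phantom256, kind):
        d = syn.make_change_pair(phantom256, kind, 1.5, seed=2)
        assert d["change_mask"].any()
        outside = ~d["change_mask"]
        assert np.array_equal(d["before"][outside], d["after"][outside])
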