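"""Unit tests for the pre-processing stage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from oracles import naive_dbscan, naive_otsu, reference_srgb_to_lab
from vesselquant import DbscanConfig, FoldThresholdConfig, VesselSpec
from vesselquant.config import ColorMask
from vesselquant.preprocess import (
    NOISE,
    NOT_FOREGROUND,
    DegenerateImageError,
    SegmentationFailure,
    clean_wall_mask,
    contrast_stretch,
    dbscan,
    detect_blood,
    detect_folds,
    fold_threshold,
    otsu_threshold,
    pixel_area,
    preprocess_image,
    remove_defects,
    rgb_to_lab,
)
from vesselquant.synthetic import generate_vessel_image


class TestRgbToLab:
    def test_white_point(self):
        lab = rgb_to_lab(np.full((1, 1, 3), 255, dtype=np.uint8))
        assert lab[0, 0, 0] == pytest.approx(100.0, abs=1e-4)
        assert abs(lab[0, 0, 1]) < 0.5 and abs(lab[0, 0, 2]) < 0.5

    def test_black_point(self):
        lab = rgb_to_lab(np.zeros((1, 1, 3), dtype=np.uint8))
        assert np.allclose(lab, 0.0, atol=1e-6)

    def test_agrees_with_independent_conversion(self, rng):
        img = rng.integers(0, 256, size=(5, 10, 3), dtype=np.uint8)
        got = rgb_to_lab(img)
        ref = reference_srgb_to_lab(img)
        assert np.abs(got - ref).max() < 0.1

    def test_l_in_range(self, rng):
        img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        L = rgb_to_lab(img)[..., 0]
        assert L.min() >= 0.0 and L.max() <= 100.0

    def test_empty_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            rgb_to_lab(np.zeros((0, 4, 3), dtype=np.uint8))


class TestFoldThreshold:
    def test_single_mode_halved(self, rng):
        L = rng.normal(40.0, 0.3, size=2000).clip(0, 100)
        assert fold_threshold(L) == pytest.approx(20.0, abs=0.5)

    def test_constant_raster_sole_peak(self):
        assert fold_threshold(np.full((10, 10), 60.0)) == pytest.approx(30.0)

    def test_trimodal_takes_first_predominant_peak(self, rng):
        # wall / outside / lumen modes; the wall peak comes first from 0
        L = np.concatenate(
            [
                rng.normal(35.0, 1.0, 3000),
                rng.normal(80.0, 1.0, 4000),
                rng.normal(95.0, 1.0, 3000),
            ]
        ).clip(0, 100)
        assert fold_threshold(L) == pytest.approx(17.5, abs=0.5)

    def test_minor_early_peak_skipped(self, rng):
        # a small dark mode below the prominence floor must not count
        L = np.concatenate(
            [rng.normal(10.0, 1.0, 200), rng.normal(60.0, 1.0, 8000)]
        ).clip(0, 100)
        assert fold_threshold(L) == pytest.approx(30.0, abs=0.5)

    def test_empty_raster_rejected(self):
        with pytest.raises(DegenerateImageError):
            fold_threshold(np.array([]))


class TestDefectMasks:
    def test_no_folds_above_threshold(self):
        lab = np.zeros((4, 4, 3))
        lab[..., 0] = 80.0
        assert not detect_folds(lab, 20.0).any()

    def test_single_dark_pixel_flagged(self):
        lab = np.zeros((4, 4, 3))
        lab[..., 0] = 80.0
        lab[2, 3, 0] = 5.0
        mask = detect_folds(lab, 20.0)
        assert mask[2, 3] and mask.sum() == 1

    def test_drawn_fold_streaks_recovered(self):
        spec = VesselSpec(n_folds=3, n_blood=0, n_dust=0, color_noise_sd=0.0, seed=4)
        rgb, truth = generate_vessel_image(spec)
        lab = rgb_to_lab(rgb)
        mask = detect_folds(lab, fold_threshold(lab[..., 0]))
        drawn = truth.fold_mask
        assert (mask & drawn).sum() >= 0.99 * drawn.sum()
        assert (mask & ~drawn).sum() <= 0.01 * mask.size

    def test_blood_radius_zero_exact_match(self):
        lab = np.zeros((2, 2, 3))
        lab[0, 0] = (35.0, 45.0, 25.0)
        mask = detect_blood(lab, ColorMask(center=(35.0, 45.0, 25.0), radius=0.0))
        assert mask[0, 0] and mask.sum() == 1

    def test_blood_huge_radius_covers_all(self, rng):
        lab = rng.uniform(-50, 100, size=(6, 6, 3))
        assert detect_blood(lab, ColorMask(radius=1e4)).all()

    def test_blood_blobs_recovered_on_synthetic(self):
        spec = VesselSpec(n_folds=0, n_blood=4, n_dust=0, seed=9)
        rgb, truth = generate_vessel_image(spec)
        mask = detect_blood(rgb_to_lab(rgb), ColorMask())
        assert (mask & truth.blood_mask).sum() >= 0.99 * truth.blood_mask.sum()


class TestRemoveDefects:
    def test_no_masks_is_identity(self, rng):
        L = rng.uniform(0, 100, (5, 5))
        out, valid = remove_defects(L, [])
        assert np.array_equal(out, L) and valid.all()

    def test_all_true_mask_zeroes_everything(self, rng):
        L = rng.uniform(0, 100, (5, 5))
        out, valid = remove_defects(L, [np.ones((5, 5), bool)])
        assert not out.any() and not valid.any()

    def test_single_flagged_pixel(self):
        L = np.full((3, 3), 50.0)
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        out, valid = remove_defects(L, [m])
        assert out[1, 1] == 0.0 and not valid[1, 1]
        assert (out[valid] == 50.0).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            remove_defects(np.zeros((3, 3)), [np.zeros((2, 2), bool)])


class TestContrastStretch:
    def test_endpoints_map_to_full_range(self):
        L = np.array([[20.0, 45.0, 70.0]])
        out = contrast_stretch(L)
        assert out[0, 0] == 0.0 and out[0, 2] == 100.0

    def test_direct_evaluation(self):
        out = contrast_stretch(np.array([[20.0, 45.0, 70.0]]))
        assert out[0, 1] == 50.0  # round(100·25/50)

    def test_extrema_taken_over_valid_pixels_only(self):
        L = np.array([[0.0, 30.0, 60.0]])
        valid = np.array([[False, True, True]])
        out = contrast_stretch(L, valid)
        assert out[0, 1] == 0.0 and out[0, 2] == 100.0 and out[0, 0] == 0.0

    def test_constant_raster_rejected(self):
        with pytest.raises(DegenerateImageError):
            contrast_stretch(np.full((4, 4), 33.0))

    @settings(derandomize=True, max_examples=50)
    @given(
        hnp.arrays(
            float,
            st.integers(2, 40),
            elements=st.floats(0, 100, allow_nan=False, width=32),
        ).filter(lambda a: np.unique(a).size >= 2)
    )
    def test_monotone_rank_preserving(self, vals):
        out = contrast_stretch(vals.reshape(1, -1)).ravel()
        order = np.argsort(vals, kind="stable")
        assert np.all(np.diff(out[order]) >= 0)
        assert out.min() == 0.0 and out.max() == 100.0


class TestOtsu:
    def test_two_valued_raster_separated(self, rng):
        vals = np.where(rng.uniform(size=200) < 0.6, 0.2, 0.8)
        T = otsu_threshold(vals.reshape(10, 20))
        assert 0.2 < T < 0.8

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(20):
            shape = (rng.integers(2, 65), rng.integers(2, 65))
            raster = rng.uniform(size=shape)
            assert otsu_threshold(raster) == naive_otsu(raster)

    def test_bimodal_mixture_threshold_between_modes(self, rng):
        vals = np.concatenate(
            [rng.normal(0.3, 0.05, 600), rng.normal(0.8, 0.05, 400)]
        ).clip(0, 1)
        assert 0.45 < otsu_threshold(vals.reshape(50, 20)) < 0.65

    def test_constant_raster_rejected(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((4, 4), 0.5))


def _check_against_naive(mask, cfg):
    labels_img = dbscan(mask, cfg)
    coords, core, ref_labels, candidates = naive_dbscan(mask, cfg.R, cfg.min_pxs)
    mine = labels_img[coords[:, 0], coords[:, 1]]
    # identical partition of core pixels, up to relabeling
    mapping = {}
    for ref, got in zip(ref_labels[core], mine[core]):
        assert got >= 0
        assert mapping.setdefault(ref, got) == got
    assert len(set(mapping.values())) == len(mapping)
    inv = {v: k for k, v in mapping.items()}
    for i in np.flatnonzero(~core):
        if i in candidates:
            # border pixel: must join one of its legitimate clusters
            assert inv[mine[i]] in candidates[i]
        else:
            # no core pixel in reach: noise
            assert mine[i] == NOISE


class TestDbscan:
    CFG = DbscanConfig(R=1.5, min_pxs=4)

    def test_isolated_pixel_is_noise(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        labels = dbscan(mask, self.CFG)
        assert labels[4, 4] == NOISE
        assert (labels == NOT_FOREGROUND).sum() == 80

    def test_solid_block_single_cluster(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        labels = dbscan(mask, self.CFG)
        fg = labels[mask]
        assert (fg == 0).all()

    def test_empty_mask_empty_labeling(self):
        labels = dbscan(np.zeros((5, 5), bool), self.CFG)
        assert (labels == NOT_FOREGROUND).all()

    @pytest.mark.parametrize("density,R,min_pxs", [(0.15, 1.5, 4), (0.3, 2.0, 6), (0.5, 3.0, 9)])
    def test_partition_matches_naive_all_pairs(self, rng, density, R, min_pxs):
        for _ in range(5):
            mask = rng.uniform(size=(40, 40)) < density
            _check_against_naive(mask, DbscanConfig(R=R, min_pxs=min_pxs))


class TestCleanWallMask:
    def _annulus(self, h=80, w=80, r_in=14, r_out=30):
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.hypot(yy - h / 2, xx - w / 2)
        return (d >= r_in) & (d <= r_out)

    def test_clean_annulus_unchanged(self):
        annulus = self._annulus()
        region = clean_wall_mask(annulus)
        assert np.array_equal(region.mask, annulus)
        assert region.a_tot == pixel_area(annulus)

    def test_specks_removed(self, rng):
        annulus = self._annulus()
        dirty = annulus.copy()
        centers = [(5, 5), (75, 10), (40, 40), (3, 70), (70, 70)]
        for _ in range(15):
            cy, cx = centers[rng.integers(0, len(centers))]
            dirty[cy + rng.integers(-2, 3), cx + rng.integers(-2, 3)] = True
        region = clean_wall_mask(dirty)
        assert np.array_equal(region.mask, annulus)

    def test_pinholes_filled(self, rng):
        annulus = self._annulus()
        holey = annulus.copy()
        # pierce 3-pixel holes well inside the ring
        yy, xx = np.mgrid[0:80, 0:80]
        d = np.hypot(yy - 40, xx - 40)
        ring = np.argwhere(annulus & (d > 18) & (d < 26))
        for idx in rng.choice(len(ring), size=6, replace=False):
            y, x = ring[idx]
            holey[y, x] = holey[y, x + 1] = holey[y + 1, x] = False
        region = clean_wall_mask(holey)
        assert np.array_equal(region.mask, annulus)

    def test_blank_image_fails(self):
        with pytest.raises(SegmentationFailure):
            clean_wall_mask(np.zeros((20, 20), bool))

    def test_never_exceeds_image_area(self, default_vessel):
        _, rgb, _ = default_vessel
        res = preprocess_image(rgb)
        assert res.wall.a_tot <= rgb.shape[0] * rgb.shape[1]
        assert res.wall.a_tot == pixel_area(res.wall.mask)


class TestPixelArea:
    def test_empty_and_small_counts(self):
        assert pixel_area(np.zeros((7, 7), bool)) == 0
        m = np.zeros((7, 7), bool)
        m[np.array([0, 1, 2, 3, 4]), np.array([6, 5, 4, 3, 2])] = True
        assert pixel_area(m) == 5

    def test_matches_per_row_accumulation(self, rng):
        m = rng.uniform(size=(33, 17)) < 0.4
        assert pixel_area(m) == sum(int(row.sum()) for row in m)


class TestEndToEndPreprocess:
    def test_wall_area_within_two_percent_on_clean_annulus(self, clean_vessel):
        _, rgb, truth = clean_vessel
        res = preprocess_image(rgb)
        true_area = pixel_area(truth.wall_mask)
        assert abs(res.wall.a_tot - true_area) <= 0.02 * true_area

    def test_thresholds_logged_in_result(self, clean_vessel):
        _, rgb, _ = clean_vessel
        res = preprocess_image(rgb)
        assert 0.0 <= res.fold_t <= 50.0
        assert 0.0 < res.otsu_T < 1.0
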