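"""Distance fields, band masks and the fluorescence parameter rules."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from rimquant.bands import (
    BandMasks,
    EmptyTumorMaskError,
    apply_stasis_override,
    build_band_masks,
    distance_to_tumor,
    pool_background,
    quantify_loaf,
    select_central_loaf,
)
from rimquant.imaging_io import AnnotationSet, FluorescenceImage

from conftest import random_mask


def brute_force_distance(tumor_mask, pixel_size_um):
    """All-pairs minimum center-to-center distance, in mm (oracle)."""
    rows, cols = np.nonzero(tumor_mask)
    tumor_pts = np.column_stack([rows, cols]).astype(float)
    out = np.zeros(tumor_mask.shape)
    for r in range(tumor_mask.shape[0]):
        for c in range(tumor_mask.shape[1]):
            d2 = ((tumor_pts - [r, c]) ** 2).sum(axis=1)
            out[r, c] = math.sqrt(d2.min())
    return out * pixel_size_um / 1000.0


class TestDistanceField:
    def test_single_pixel_neighbours(self):
        tumor = np.zeros((5, 5), dtype=bool)
        tumor[2, 2] = True
        d = distance_to_tumor(tumor, pixel_size_um=1000.0)
        assert d[2, 2] == 0.0
        assert d[1, 2] == d[2, 1] == d[3, 2] == d[2, 3] == pytest.approx(1.0)
        assert d[1, 1] == pytest.approx(math.sqrt(2))

    def test_all_tumor_grid_is_zero(self):
        d = distance_to_tumor(np.ones((4, 4), dtype=bool), pixel_size_um=85.0)
        assert (d == 0).all()

    def test_empty_tumor_mask_raises(self):
        with pytest.raises(EmptyTumorMaskError, match="empty tumor mask"):
            distance_to_tumor(np.zeros((3, 3), dtype=bool), 85.0)

    def test_matches_all_pairs_oracle_on_random_masks(self, rng):
        for _ in range(10):
            tumor = random_mask(rng, (16, 16), density=0.08)
            d = distance_to_tumor(tumor, pixel_size_um=85.0)
            expected = brute_force_distance(tumor, 85.0)
            np.testing.assert_allclose(d, expected, atol=1e-9)


class TestBandMasks:
    def test_lattice_disc_rim_count(self):
        # 1 mm pixels, single center tumor pixel: 29 lattice points with
        # d <= 3 including the center, hence 28 rim pixels
        tumor = np.zeros((21, 21), dtype=bool)
        tumor[10, 10] = True
        tissue = np.ones((21, 21), dtype=bool)
        masks = build_band_masks(tumor, tissue, pixel_size_um=1000.0)
        assert masks.rim_mask.sum() == 28

    def test_partition_of_tissue(self, rng):
        tumor = random_mask(rng, (40, 40), density=0.05)
        tissue = random_mask(rng, (40, 40), density=0.7) | tumor
        masks = build_band_masks(tumor, tissue, pixel_size_um=900.0)
        total = (
            masks.tumor_mask.astype(int)
            + masks.rim_mask.astype(int)
            + masks.gap_mask.astype(int)
            + masks.background_mask.astype(int)
        )
        assert (total == tissue.astype(int)).all()  # exact disjoint cover

    def test_thresholds_inclusive_on_physical_distance(self):
        tumor = np.zeros((1, 12), dtype=bool)
        tumor[0, 0] = True
        tissue = np.ones((1, 12), dtype=bool)
        masks = build_band_masks(tumor, tissue, pixel_size_um=1000.0)
        d = masks.distance_mm[0]
        assert masks.rim_mask[0, 3] and d[3] == 3.0  # "up to 3 mm" inclusive
        assert masks.background_mask[0, 5] and d[5] == 5.0  # "from 5 mm" inclusive
        assert masks.gap_mask[0, 4]

    def test_coincident_thresholds_leave_no_gap(self):
        tumor = np.zeros((15, 15), dtype=bool)
        tumor[7, 7] = True
        tissue = np.ones((15, 15), dtype=bool)
        masks = build_band_masks(tumor, tissue, 1000.0, rim_mm=3.0, background_from_mm=3.0)
        assert masks.gap_mask.sum() == 0
        nontumor = tissue & ~tumor
        assert ((masks.rim_mask | masks.background_mask) == nontumor).all()

    def test_tissue_within_rim_distance_gives_empty_background(self):
        tumor = np.zeros((5, 5), dtype=bool)
        tumor[2, 2] = True
        tissue = np.ones((5, 5), dtype=bool)
        masks = build_band_masks(tumor, tissue, pixel_size_um=1000.0)
        assert masks.background_mask.sum() == 0

    def test_rim_mm_larger_than_background_from_mm_rejected(self):
        tumor = np.zeros((5, 5), dtype=bool)
        tumor[2, 2] = True
        with pytest.raises(ValueError, match="rim_mm"):
            build_band_masks(tumor, np.ones((5, 5), bool), 1000.0, rim_mm=6, background_from_mm=5)

    def test_monotonicity_in_band_parameters(self, rng):
        tumor = random_mask(rng, (32, 32), density=0.03)
        tissue = np.ones((32, 32), dtype=bool)
        rims = [
            build_band_masks(tumor, tissue, 500.0, rim_mm=r, background_from_mm=8.0).rim_mask
            for r in (1.0, 2.0, 4.0)
        ]
        assert (rims[0] <= rims[1]).all() and (rims[1] <= rims[2]).all()
        bgs = [
            build_band_masks(tumor, tissue, 500.0, rim_mm=1.0, background_from_mm=b).background_mask
            for b in (2.0, 4.0, 8.0)
        ]
        assert (bgs[2] <= bgs[1]).all() and (bgs[1] <= bgs[0]).all()


def _simple_masks():
    tumor = np.zeros((30, 30), dtype=bool)
    tumor[14:16, 14:16] = True
    tissue = np.ones((30, 30), dtype=bool)
    return build_band_masks(tumor, tissue, pixel_size_um=500.0)


class TestQuantify:
    def test_flat_image_gives_unit_sbr(self, flat_image):
        tumor = np.zeros((64, 64), dtype=bool)
        tumor[30:34, 30:34] = True
        masks = build_band_masks(tumor, np.ones((64, 64), bool), 1000.0, 3.0, 5.0)
        r = quantify_loaf(flat_image, masks)
        assert r.msfi_au == r.mbfi_au == r.max_intensity_au == 3.5
        assert r.sbr == 1.0

    def test_hand_computed_means(self):
        tumor = np.zeros((1, 9), dtype=bool)
        tumor[0, 0] = True
        tissue = np.zeros((1, 9), dtype=bool)
        tissue[0, [0, 1, 2, 5, 6, 7, 8]] = True  # rim at d=1,2 ; background at d>=5
        masks = build_band_masks(tumor, tissue, pixel_size_um=1000.0)
        px = np.array([[9.0, 2.0, 4.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]])
        img = FluorescenceImage(pixels=px, pixel_size_um=1000.0)
        r = quantify_loaf(img, masks)
        assert r.msfi_au == 3.0 and r.mbfi_au == 1.0 and r.sbr == 3.0

    def test_intensity_homogeneity(self, rng):
        masks = _simple_masks()
        px = rng.uniform(0.1, 2.0, size=(30, 30))
        img1 = FluorescenceImage(pixels=px, pixel_size_um=500.0)
        img2 = FluorescenceImage(pixels=3.0 * px, pixel_size_um=500.0)
        r1, r2 = quantify_loaf(img1, masks), quantify_loaf(img2, masks)
        assert r2.msfi_au == pytest.approx(3 * r1.msfi_au)
        assert r2.mbfi_au == pytest.approx(3 * r1.mbfi_au)
        assert r2.max_intensity_au == pytest.approx(3 * r1.max_intensity_au)
        assert r2.sbr == pytest.approx(r1.sbr)

    def test_background_area_straddles_100_mm2_at_85um(self):
        # 13 841 pixels x (0.085 mm)^2 = 100.0012 mm2 ; one pixel fewer is below
        area = 0.085**2
        assert 13841 * area >= 100.0
        assert 13840 * area < 100.0

    def test_max_scope_options(self):
        masks = _simple_masks()
        px = np.full((30, 30), 1.0)
        px[0, 0] = 50.0  # bright frame-edge artifact outside any mask? tissue covers all here
        img = FluorescenceImage(pixels=px, pixel_size_um=500.0)
        assert quantify_loaf(img, masks, max_scope="image").max_intensity_au == 50.0
        assert quantify_loaf(img, masks, max_scope="rim").max_intensity_au == 1.0

    def test_empty_rim_is_an_error(self):
        masks = _simple_masks()
        masks.rim_mask[:] = False
        img = FluorescenceImage(pixels=np.ones((30, 30)), pixel_size_um=500.0)
        with pytest.raises(ValueError, match="no rim pixels"):
            quantify_loaf(img, masks)


class TestStasisOverride:
    def _setup(self):
        masks = _simple_masks()
        px = np.ones((30, 30))
        bg = masks.background_mask
        rows, cols = np.nonzero(bg)
        half = len(rows) // 2
        px[rows[:half], cols[:half]] = 10.0  # stasis blob over half the background
        img = FluorescenceImage(pixels=px, pixel_size_um=500.0)
        naive = quantify_loaf(img, masks)
        stasis_poly = [
            box(c, r, c + 1, r + 1) for r, c in zip(rows[:half], cols[:half])
        ]
        return img, masks, naive, stasis_poly, rows, cols, half

    def test_stasis_subtraction_restores_background_mean(self):
        img, masks, naive, stasis_poly, *_ = self._setup()
        assert naive.mbfi_au > 5.0  # contaminated
        ann = AnnotationSet(tumor=[], tissue=[], stasis=stasis_poly)
        fixed = apply_stasis_override(img, masks, ann, naive)
        assert fixed.mbfi_au == pytest.approx(1.0)
        assert fixed.stasis_override
        assert fixed.sbr == pytest.approx(fixed.msfi_au / 1.0)

    def test_override_polygon_takes_precedence(self):
        img, masks, naive, _, rows, cols, half = self._setup()
        clean = [box(c, r, c + 1, r + 1) for r, c in zip(rows[half:], cols[half:])]
        ann = AnnotationSet(tumor=[], tissue=[], background_override=clean)
        fixed = apply_stasis_override(img, masks, ann, naive)
        assert fixed.mbfi_au == pytest.approx(1.0)

    def test_no_annotation_returns_identity(self):
        img, masks, naive, *_ = self._setup()
        same = apply_stasis_override(img, masks, AnnotationSet(), naive)
        assert same is naive and not same.stasis_override

    def test_empty_override_region_invalid(self):
        img, masks, naive, *_ = self._setup()
        ann = AnnotationSet(background_override=[box(14, 14, 16, 16)])  # at tumor, d=0
        with pytest.raises(ValueError, match="override region invalid"):
            apply_stasis_override(img, masks, ann, naive)


def _loaf_with_background(n_bg_pixels, value, pixel_size_um=1000.0):
    """A fake loaf exposing only a background mask of given size and value."""
    side = int(np.ceil(np.sqrt(n_bg_pixels)))
    px = np.full((side, side), float(value))
    mask = np.zeros((side, side), dtype=bool)
    mask.ravel()[:n_bg_pixels] = True
    img = FluorescenceImage(pixels=px, pixel_size_um=pixel_size_um, loaf_id="extra")
    return img, mask


class TestPoolBackground:
    def _primary(self, n_bg, value=1.0):
        tumor = np.zeros((40, 40), dtype=bool)
        tumor[0, 0] = True
        tissue = np.zeros((40, 40), dtype=bool)
        tissue[0, 0] = tissue[0, 1] = True  # tumor + one rim pixel
        flat_rows = np.arange(40 * 40 - 1, 40 * 40 - 1 - n_bg, -1)
        tissue.ravel()[flat_rows] = True
        masks = build_band_masks(tumor, tissue, pixel_size_um=1000.0)
        assert masks.background_mask.sum() == n_bg
        px = np.full((40, 40), value)
        px[0, 1] = 2.0
        img = FluorescenceImage(pixels=px, pixel_size_um=1000.0, loaf_id="primary")
        return img, masks, quantify_loaf(img, masks)

    def test_sufficient_background_untouched(self):
        img, masks, result = self._primary(n_bg=120)  # 120 mm2 at 1 mm pixels
        pooled = pool_background(result, img, masks, [], min_area_mm2=100.0)
        assert pooled is result
        assert not pooled.background_pooled and not pooled.excluded_insufficient_tissue

    def test_pooled_mean_is_pixel_weighted(self):
        img, masks, result = self._primary(n_bg=40, value=1.0)
        extra = _loaf_with_background(80, 2.0)
        pooled = pool_background(result, img, masks, [extra], min_area_mm2=100.0)
        assert pooled.background_pooled
        assert pooled.mbfi_au == pytest.approx((40 * 1.0 + 80 * 2.0) / 120)
        assert pooled.background_area_mm2 == pytest.approx(120.0)
        assert pooled.loaf_ids_used == ["primary", "extra"]

    def test_pooling_stops_once_area_reached(self):
        img, masks, result = self._primary(n_bg=40)
        extras = [_loaf_with_background(80, 2.0), _loaf_with_background(500, 9.0)]
        pooled = pool_background(result, img, masks, extras, min_area_mm2=100.0)
        assert pooled.mbfi_au == pytest.approx((40 + 160) / 120)  # third loaf unused

    def test_insufficient_total_area_excludes(self):
        img, masks, result = self._primary(n_bg=40)
        extra = _loaf_with_background(15, 2.0)
        pooled = pool_background(result, img, masks, [extra], min_area_mm2=100.0)
        assert pooled.excluded_insufficient_tissue
        assert math.isnan(pooled.mbfi_au) and math.isnan(pooled.sbr)


class TestSelectCentralLoaf:
    def _loaf(self, tumor_px):
        img = FluorescenceImage(pixels=np.ones((20, 20)), pixel_size_um=85.0)
        side = math.isqrt(tumor_px)
        ann = AnnotationSet(tumor=[box(0, 0, side, tumor_px / side)], tissue=[box(0, 0, 20, 20)])
        return img, ann

    def test_argmax_tumor_area(self):
        loaves = [self._loaf(a) for a in (10, 55, 30)]
        assert select_central_loaf(loaves) == 1

    def test_single_loaf(self):
        assert select_central_loaf([self._loaf(9)]) == 0

    def test_tie_breaks_to_lowest_index(self):
        assert select_central_loaf([self._loaf(40), self._loaf(40)]) == 0

    def test_no_tumor_anywhere_raises(self):
        img = FluorescenceImage(pixels=np.ones((5, 5)), pixel_size_um=85.0)
        ann = AnnotationSet(tissue=[box(0, 0, 5, 5)])
        with pytest.raises(ValueError, match="tumor"):
            select_central_loaf([(img, ann)])
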