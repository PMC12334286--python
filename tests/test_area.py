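"""Area quantification: pixel counting, physical scaling, exactness."""

import numpy as np
import pytest

from tumorseg.area import area_report, count_tumor_pixels, pixel_area, tumor_area
from tumorseg.pipeline import resize_sample
from tumorseg.sample import PixelSpacing


class TestCountTumorPixels:
    def test_empty_mask(self):
        assert count_tumor_pixels(np.zeros((6, 6), dtype=np.uint8)) == 0

    def test_diagonal_mask(self):
        assert count_tumor_pixels(np.eye(3, dtype=np.uint8)) == 3

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            count_tumor_pixels(np.array([[0, 2]]))

    def test_matches_generator_bookkeeping(self, phantom_batch):
        _, samples = phantom_batch
        for s in samples:
            assert count_tumor_pixels(s.mask) == int(s.mask.sum())


class TestPixelArea:
    @pytest.mark.parametrize("sx,sy,want", [(1.0, 1.0, 1.0), (0.5, 0.5, 0.25),
                                            (0.8, 1.2, 0.96)])
    def test_products(self, sx, sy, want):
        assert pixel_area(PixelSpacing(sx, sy)) == pytest.approx(want)

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            PixelSpacing(0.0, 1.0)


class TestTumorArea:
    def test_hundred_pixels_at_half_millimetre(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask.flat[:100] = 1
        res = tumor_area(mask, PixelSpacing(0.5, 0.5), "s")
        assert res.tumor_area == pytest.approx(25.0)
        assert res.pixel_count == 100

    def test_empty_mask_zero_area(self):
        res = tumor_area(np.zeros((8, 8), dtype=np.uint8), PixelSpacing(3.0, 2.0))
        assert res.tumor_area == 0.0

    def test_unit_spacing_equals_pixel_count(self, rng):
        mask = (rng.random((16, 16)) < 0.4).astype(np.uint8)
        res = tumor_area(mask, PixelSpacing(1.0, 1.0))
        assert res.tumor_area == res.pixel_count

    def test_quadratic_spacing_scaling(self, rng):
        mask = (rng.random((16, 16)) < 0.4).astype(np.uint8)
        base = tumor_area(mask, PixelSpacing(0.7, 1.1)).tumor_area
        for k in (0.5, 2.0, 3.0):
            scaled = tumor_area(mask, PixelSpacing(0.7 * k, 1.1 * k)).tumor_area
            assert scaled == pytest.approx(k * k * base)

    def test_disjoint_mask_additivity(self, rng):
        a = np.zeros((16, 16), dtype=np.uint8)
        b = np.zeros((16, 16), dtype=np.uint8)
        a[:8] = (rng.random((8, 16)) < 0.5).astype(np.uint8)
        b[8:] = (rng.random((8, 16)) < 0.5).astype(np.uint8)
        sp = PixelSpacing(0.9, 1.3)
        assert tumor_area(a | b, sp).tumor_area == pytest.approx(
            tumor_area(a, sp).tumor_area + tumor_area(b, sp).tumor_area)

    def test_min_blob_filter_off_by_default(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[0, 0] = 1  # single-pixel speck counts by default
        assert tumor_area(mask, PixelSpacing(1, 1)).pixel_count == 1
        assert tumor_area(mask, PixelSpacing(1, 1), min_blob_size=2).pixel_count == 0


class TestAreaReport:
    def test_single_sample_single_row(self):
        table = area_report([(np.eye(4, dtype=np.uint8), PixelSpacing(1, 1), "a")])
        assert len(table) == 1
        assert table.loc[0, "area_mm2"] == pytest.approx(4.0)

    def test_spacing_ratio_between_identical_masks(self, rng):
        mask = (rng.random((8, 8)) < 0.5).astype(np.uint8)
        table = area_report([(mask, PixelSpacing(1.0, 1.0), "a"),
                             (mask, PixelSpacing(2.0, 2.0), "b")])
        assert table.loc[1, "area_mm2"] == pytest.approx(4 * table.loc[0, "area_mm2"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            area_report([])

    def test_phantom_dataset_exactness(self, phantom_batch):
        spec, samples = phantom_batch
        table = area_report([(s.mask, s.spacing, s.id) for s in samples])
        for row, s in zip(table.itertuples(), sorted(samples, key=lambda s: s.id)):
            assert row.area_mm2 == int(s.mask.sum()) * spec.pixel_spacing_x * spec.pixel_spacing_y


def test_resize_consistency_bounded_by_boundary_ring(phantom_batch):
    """Nearest-neighbor downsampling changes physical area by less than one
    boundary ring of coarse pixels on convex lesions."""
    from scipy import ndimage

    _, samples = phantom_batch
    checked = 0
    for s in samples:
        if s.mask.sum() < 200:
            continue
        small = resize_sample(s, 64, 64)
        a_orig = tumor_area(s.mask, s.spacing).tumor_area
        a_small = tumor_area(small.mask, small.spacing).tumor_area
        ring = small.mask & ~ndimage.binary_erosion(small.mask)
        bound = ring.sum() * pixel_area(small.spacing)
        assert abs(a_orig - a_small) < max(bound, pixel_area(small.spacing))
        checked += 1
        if checked >= 10:
            break
    assert checked >= 5
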