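"""Sector sampling, multi-seed growth, boundary interpolation."""

import numpy as np
import pytest
from scipy import ndimage

from eagseg import (
    GrowthConfig,
    dice,
    geometric_center,
    grow_region,
    interpolate_boundaries,
    multi_start_growth,
    sample_sector_points,
)
from conftest import disk


class TestGeometricCenter:
    def test_single_pixel(self):
        mask = np.zeros((6, 8), bool)
        mask[3, 4] = True
        assert geometric_center(mask) == pytest.approx((3.0, 4.0))

    def test_filled_square(self):
        mask = np.zeros((5, 5), bool)
        mask[:, :] = True
        assert geometric_center(mask) == pytest.approx((2.0, 2.0))

    def test_l_shape(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[0, 1] = mask[1, 0] = True
        assert geometric_center(mask) == pytest.approx((1 / 3, 1 / 3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            geometric_center(np.zeros((3, 3), bool))


class TestSectorSampling:
    def test_disk_yields_point_per_quadrant(self):
        mask = disk((41, 41), (20, 20), 12)
        rng = np.random.default_rng(4)
        sample = sample_sector_points(mask, (20, 20), rng)
        assert sample.sector_count == 4
        assert len(sample.points) == 4
        signs = set()
        for p in sample.points:
            assert mask[p]
            signs.add((p[0] >= 20, p[1] >= 20))
        assert len(signs) == 4  # one point in each distinct quadrant

    def test_reproducible_with_same_seed(self):
        mask = disk((41, 41), (20, 20), 12)
        a = sample_sector_points(mask, (20, 20), np.random.default_rng(7))
        b = sample_sector_points(mask, (20, 20), np.random.default_rng(7))
        assert a.points == b.points

    def test_single_pixel_mask_degenerates(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        with pytest.warns(UserWarning):
            sample = sample_sector_points(mask, (4, 4), np.random.default_rng(0))
        assert sample.points == [(4, 4)]

    def test_octants_in_3d(self):
        mask = disk((21, 21, 21), (10, 10, 10), 7)
        sample = sample_sector_points(mask, (10, 10, 10), np.random.default_rng(1))
        assert sample.sector_count == 8
        assert len(sample.points) == 8


class TestMultiStart:
    def _uniform_tumor(self):
        img = np.full((41, 41), 0.1)
        tumor = disk((41, 41), (20, 20), 9)
        img[tumor] = 0.8
        return img, tumor

    def test_homogeneous_tumor_near_identical_masks(self):
        img, tumor = self._uniform_tumor()
        cfg = GrowthConfig(threshold=0.15)
        rng = np.random.default_rng(2)
        sample = sample_sector_points(tumor, (20, 20), rng)
        seeds = [(20, 20)] + sample.points
        assert len(seeds) == 5
        results = multi_start_growth(img, seeds, cfg, lambda s: grow_region(img, s, cfg))
        for i in range(len(results)):
            for j in range(i + 1, len(results)):
                assert dice(results[i].mask, results[j].mask) >= 0.95

    def test_single_seed_reduces_to_primary(self):
        img, tumor = self._uniform_tumor()
        cfg = GrowthConfig(threshold=0.15)
        results = multi_start_growth(img, [(20, 20)], cfg, lambda s: grow_region(img, s, cfg))
        assert len(results) == 1
        assert np.array_equal(results[0].mask, grow_region(img, (20, 20), cfg).mask)

    def test_each_result_contains_its_seed(self):
        img, tumor = self._uniform_tumor()
        cfg = GrowthConfig(threshold=0.15)
        seeds = [(20, 20), (16, 18), (24, 23), (18, 24), (23, 17)]
        results = multi_start_growth(img, seeds, cfg, lambda s: grow_region(img, s, cfg))
        for seed, res in zip(seeds, results):
            assert res.mask[seed]

    def test_failing_seed_dropped_with_warning(self):
        img, tumor = self._uniform_tumor()
        lung = tumor
        cfg = GrowthConfig(threshold=0.15, lung_mask=lung)
        with pytest.warns(UserWarning, match="failed"):
            results = multi_start_growth(
                img, [(20, 20), (1, 1)], cfg, lambda s: grow_region(img, s, cfg)
            )
        assert len(results) == 1

    def test_all_seeds_failing_raises(self):
        img, tumor = self._uniform_tumor()
        cfg = GrowthConfig(threshold=0.15, lung_mask=tumor)
        with pytest.warns(UserWarning):
            with pytest.raises(RuntimeError):
                multi_start_growth(
                    img, [(1, 1)], cfg, lambda s: grow_region(img, s, cfg)
                )


class TestInterpolation:
    def test_single_mask_identity(self):
        d = disk((40, 40), (20, 20), 8)
        assert dice(interpolate_boundaries([d], (20, 20), 360), d) >= 0.98

    def test_identical_masks_identity(self):
        d = disk((40, 40), (20, 20), 8)
        out = interpolate_boundaries([d, d, d], (20, 20), 360)
        assert dice(out, d) >= 0.98

    def test_concentric_disks_average_radius(self):
        d4 = disk((40, 40), (20, 20), 4)
        d8 = disk((40, 40), (20, 20), 8)
        d6 = disk((40, 40), (20, 20), 6)
        out = interpolate_boundaries([d4, d8], (20, 20), 360)
        assert dice(out, d6) >= 0.9

    def test_contained_in_union_dilated_by_one(self):
        d4 = disk((40, 40), (22, 18), 5)
        d8 = disk((40, 40), (20, 20), 9)
        out = interpolate_boundaries([d4, d8], (20, 20), 360)
        union = ndimage.binary_dilation(d4 | d8, structure=np.ones((3, 3), bool))
        assert np.all(~out | union)

    def test_majority_vote(self):
        d_small = disk((40, 40), (20, 20), 4)
        d_big = disk((40, 40), (20, 20), 8)
        out = interpolate_boundaries(
            [d_small, d_small, d_big], (20, 20), method="majority"
        )
        assert np.array_equal(out, d_small)

    def test_center_outside_all_masks_rejected(self):
        d = disk((40, 40), (10, 10), 4)
        with pytest.raises(ValueError):
            interpolate_boundaries([d], (30, 30), 360)

    def test_3d_identity(self):
        d = disk((24, 24, 24), (12, 12, 12), 6)
        out = interpolate_boundaries([d], (12, 12, 12), 32)
        assert dice(out, d) >= 0.95
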