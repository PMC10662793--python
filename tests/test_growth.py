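"""Braided growth kernel: thresholding, acceptance band, traces."""

import numpy as np
import pytest
from scipy import ndimage

from eagseg import (
    GrowthConfig,
    compute_threshold,
    grow_region,
    otsu_level,
    update_comparison_value,
)


def brute_force_otsu_variance(values, level):
    """Between-class variance achieved by cutting a 256-bin histogram at
    ``level``, plus the maximum achievable variance over all cuts."""
    v = np.asarray(values, float).ravel()
    hist, edges = np.histogram(v, bins=256, range=(v.min(), v.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    best = -1.0
    at_level = None
    for i in range(1, 256):
        w0, w1 = w[:i].sum(), w[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (w[:i] * centers[:i]).sum() / w0
        m1 = (w[i:] * centers[i:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        best = max(best, var)
        if at_level is None and centers[i - 1] >= level - 1e-12:
            at_level = var
    return at_level, best


class TestOtsu:
    def test_bimodal_separation(self):
        values = np.array([0.1] * 50 + [0.9] * 50)
        level = otsu_level(values)
        assert 0.1 < level < 0.9

    def test_constant_collection_returns_value(self):
        assert otsu_level(np.full(40, 0.7)) == pytest.approx(0.7)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            otsu_level([])

    def test_matches_brute_force_variance_maximum(self):
        # Gaussian mixture; the returned cut must achieve the maximal
        # between-class variance over all 256 histogram cut points (the
        # empty inter-mode gap makes the optimum a plateau, so optimality
        # of the achieved variance is the invariant, not the cut index).
        rng = np.random.default_rng(42)
        values = np.clip(
            np.concatenate([rng.normal(0.2, 0.05, 500), rng.normal(0.8, 0.05, 500)]),
            0,
            1,
        )
        level = otsu_level(values)
        at_level, best = brute_force_otsu_variance(values, level)
        assert at_level == pytest.approx(best, rel=1e-9)


class TestComputeThreshold:
    def test_fraction_of_precomputed_level(self):
        assert compute_threshold(0.5, 1.0) == pytest.approx(0.5)

    def test_collection_input_uses_otsu(self):
        values = np.array([0.1] * 50 + [0.9] * 50)
        assert compute_threshold(values, 1.0) == pytest.approx(otsu_level(values))

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_fraction_out_of_range(self, fraction):
        with pytest.raises(ValueError):
            compute_threshold(0.5, fraction)


class TestComparisonValue:
    @pytest.mark.parametrize(
        "values,mode,expected",
        [
            ([0.2, 0.4, 0.6], "mean", 0.4),
            ([0.1, 0.9, 0.5], "median", 0.5),
            ([0.7], "mean", 0.7),
            ([0.7], "median", 0.7),
        ],
    )
    def test_examples(self, values, mode, expected):
        assert update_comparison_value(values, mode) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            update_comparison_value([], "mean")


class TestGrowRegion:
    def test_constant_image_fills_everything(self):
        img = np.full((12, 15), 0.4)
        res = grow_region(img, (5, 5), GrowthConfig(threshold=0.1))
        assert res.mask.all()
        assert res.trace_frontier[-1] == 0

    def test_constant_image_fills_lung_mask_only(self):
        img = np.full((12, 12), 0.4)
        lung = np.zeros((12, 12), bool)
        lung[3:9, 3:9] = True
        res = grow_region(img, (5, 5), GrowthConfig(threshold=0.1, lung_mask=lung))
        assert np.array_equal(res.mask, lung)

    def test_isolated_seed(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        res = grow_region(img, (4, 4), GrowthConfig(threshold=0.2))
        assert res.mask.sum() == 1
        assert res.mask[4, 4]
        assert [tuple(p) for p in res.boundary] == [(4, 4)]

    def test_printed_grid_exact_block(self):
        # central 3x3 block at 0.9, ring at 0.5, background 0.1
        img = np.full((7, 7), 0.1)
        img[1:6, 1:6] = 0.5
        img[2:5, 2:5] = 0.9
        res = grow_region(img, (3, 3), GrowthConfig(threshold=0.15))
        expected = np.zeros((7, 7), bool)
        expected[2:5, 2:5] = True
        assert np.array_equal(res.mask, expected)

    def test_threshold_zero_limiting_case(self):
        img = np.full((8, 8), 0.3)
        img[0, 0] = 0.9
        res = grow_region(img, (4, 4), GrowthConfig(threshold=0.0))
        assert res.mask.sum() == 63  # every connected pixel equal to the seed

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            img = rng.random((16, 16))
            seed = tuple(rng.integers(0, 16, 2))
            t1, t2 = sorted(rng.uniform(0.02, 0.4, 2))
            m1 = grow_region(img, seed, GrowthConfig(threshold=t1)).mask
            m2 = grow_region(img, seed, GrowthConfig(threshold=t2)).mask
            assert np.all(~m1 | m2)

    def test_radius_constraint(self):
        img = np.full((31, 31), 0.5)
        cfg = GrowthConfig(threshold=0.1, max_radius=5.0, radius_factor=2.0)
        res = grow_region(img, (15, 15), cfg)
        coords = np.argwhere(res.mask)
        dist = np.sqrt(((coords - (15, 15)) ** 2).sum(axis=1))
        assert dist.max() <= 10.0 + 1e-9
        assert res.mask.sum() > 200  # the full disk of radius 10

    def test_lung_mask_never_left(self):
        rng = np.random.default_rng(9)
        img = rng.random((20, 20))
        lung = disk_like = np.zeros((20, 20), bool)
        disk_like[4:16, 4:16] = True
        res = grow_region(img, (10, 10), GrowthConfig(threshold=0.9, lung_mask=lung))
        assert np.all(~res.mask | lung)

    def test_median_update_matches_none_on_symmetric_noise(self):
        rng = np.random.default_rng(0)
        img = np.clip(0.5 + rng.normal(0, 0.05, (32, 32)), 0, 1)
        m_none = grow_region(img, (16, 16), GrowthConfig(threshold=0.15)).mask
        m_med = grow_region(
            img, (16, 16), GrowthConfig(threshold=0.15, compare_update="median")
        ).mask
        assert (m_none ^ m_med).sum() < 0.05 * m_none.size

    def test_boundary_points_have_outside_neighbor(self):
        rng = np.random.default_rng(3)
        img = rng.random((16, 16))
        res = grow_region(img, (8, 8), GrowthConfig(threshold=0.3))
        mask = res.mask
        padded = np.pad(mask, 1)
        for p in res.boundary:
            assert mask[tuple(p)]
            nb = padded[p[0] : p[0] + 3, p[1] : p[1] + 3]
            assert not nb.all()

    @pytest.mark.parametrize(
        "seed,err",
        [((99, 99), "outside image"), ((2, 2), "outside the lung")],
    )
    def test_seed_validation(self, seed, err):
        img = np.full((10, 10), 0.5)
        lung = np.zeros((10, 10), bool)
        lung[5:8, 5:8] = True
        with pytest.raises(ValueError, match=err):
            grow_region(img, seed, GrowthConfig(threshold=0.1, lung_mask=lung))

    def test_nan_seed_rejected(self):
        img = np.full((6, 6), 0.5)
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            grow_region(img, (3, 3), GrowthConfig(threshold=0.1))

    def test_flood_fill_oracle_spot_checks(self):
        rng = np.random.default_rng(77)
        for shape in [(16, 16), (8, 8, 8)]:
            for _ in range(5):
                img = rng.random(shape)
                seed = tuple(rng.integers(0, s) for s in shape)
                t = float(rng.uniform(0.05, 0.35))
                res = grow_region(img, seed, GrowthConfig(threshold=t))
                qual = np.abs(img - img[seed]) <= t
                lab, _ = ndimage.label(qual, structure=np.ones((3,) * len(shape), bool))
                assert np.array_equal(res.mask, lab == lab[seed])
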