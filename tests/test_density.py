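import numpy as np
import pytest

from massdesc.density import (
    DensityParams,
    cluster_density,
    density_map,
    density_relation,
    describe_density,
    homogeneity_map,
    surrounding_ring,
)
from massdesc.io import BoundingBox, GrayImage


def checkerboard(mult=1, size=16):
    """Two-level board whose levels fall `mult` quantization bins apart
    (N=32 over the 0..255 range -> bin width 8)."""
    return (np.indices((size, size)).sum(0) % 2) * 8.0 * mult


class TestHomogeneityMap:
    def test_constant_patch_is_one(self):
        H = homogeneity_map(np.full((16, 16), 123.0), window=5)
        assert np.all(H == 1.0)

    def test_adjacent_bin_checkerboard_is_half(self):
        H = homogeneity_map(checkerboard(1), window=5, n_levels=32, value_range=(0, 255))
        assert np.all(H == 0.5)

    def test_decreases_with_bin_distance(self):
        means = [
            homogeneity_map(checkerboard(m), window=5, n_levels=32, value_range=(0, 255)).mean()
            for m in (1, 2, 3)
        ]
        assert means[0] > means[1] > means[2]
        assert means[0] == pytest.approx(0.5)
        assert means[1] == pytest.approx(1 / (1 + 4))

    def test_window_larger_than_patch_raises(self):
        with pytest.raises(ValueError):
            homogeneity_map(np.zeros((8, 8)), window=11)


class TestDensityMap:
    def test_constant_patch_equals_intensity(self):
        patch = np.full((16, 16), 88.0)
        assert np.array_equal(density_map(patch), patch)

    def test_bounded_by_intensity(self):
        rng = np.random.default_rng(2)
        patch = rng.integers(0, 256, (32, 32)).astype(float)
        dm = density_map(patch)
        assert np.all(dm <= patch + 1e-9) and np.all(dm >= 0)

    def test_checkerboard_halves_intensity(self):
        patch = checkerboard(1) + 100  # values 100/108, one bin apart
        dm = density_map(GrayImage(patch.astype(np.uint8), L=255, id="c"),
                         DensityParams(window=5), value_range=(0, 255))
        assert np.allclose(dm, 0.5 * patch)


class TestClusterDensity:
    def test_four_plateaus_recovered_in_order(self):
        img = np.zeros((40, 40))
        for i, v in enumerate((40, 100, 160, 220)):
            img[:, i * 10 : (i + 1) * 10] = v
        classes = cluster_density(img)
        for i in range(4):
            assert np.all(classes[:, i * 10 : (i + 1) * 10] == i + 1)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(100, 30, (30, 30))
        assert np.array_equal(cluster_density(vals, seed=3), cluster_density(vals, seed=3))

    def test_monotone_transform_preserves_class_order(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(m, 2, 200) for m in (20, 60, 120, 200)])
        c1 = cluster_density(vals)
        c2 = cluster_density(vals * 2 + 5)
        assert np.array_equal(c1, c2)

    def test_few_distinct_values_assigned_by_order(self):
        img = np.where(np.indices((10, 10)).sum(0) % 2 == 0, 10.0, 50.0)
        with pytest.warns(UserWarning, match="distinct"):
            classes = cluster_density(img)
        assert set(np.unique(classes)) == {1, 2}
        assert np.all(classes[img == 10] == 1)

    def test_kmeans_switch(self):
        img = np.zeros((20, 20))
        for i, v in enumerate((40, 100, 160, 220)):
            img[:, i * 5 : (i + 1) * 5] = v
        classes = cluster_density(img, method="kmeans", seed=0)
        assert np.all(classes[:, :5] == 1) and np.all(classes[:, 15:] == 4)


class TestSurroundingRing:
    def test_twenty_percent_expansion(self):
        box = BoundingBox(150, 150, 100, 100)
        mask = np.zeros((400, 400), bool)
        mask[175:225, 175:225] = True
        ring, expanded = surrounding_ring(box, mask.shape, mask)
        assert (expanded.height, expanded.width) == (140, 140)
        assert not ring[mask].any()
        assert ring.sum() == 140 * 140 - mask.sum()

    def test_corner_box_clipped_but_nonempty(self):
        box = BoundingBox(0, 0, 20, 20)
        mask = np.zeros((100, 100), bool)
        mask[2:10, 2:10] = True
        ring, expanded = surrounding_ring(box, mask.shape, mask)
        assert expanded.row0 == 0 and expanded.col0 == 0
        assert ring.any()

    def test_zero_expansion_is_box_minus_mask(self):
        box = BoundingBox(10, 10, 20, 20)
        mask = np.zeros((60, 60), bool)
        mask[15:25, 15:25] = True
        ring, _ = surrounding_ring(box, mask.shape, mask, expansion=0.0)
        assert ring.sum() == 20 * 20 - 100


class TestDensityRelation:
    def rel(self, inside, ring_cls):
        classes = np.full((30, 30), ring_cls)
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        classes[mask] = inside
        ring = ~mask
        return density_relation(classes, mask, ring)

    def test_three_level_rule(self):
        assert self.rel(4, 2).dms == 3
        assert self.rel(1, 3).dms == 1
        assert self.rel(2, 2).dms == 2

    def test_identical_distributions_are_equal(self):
        rng = np.random.default_rng(0)
        classes = rng.integers(1, 5, (30, 30))
        mask = np.zeros((30, 30), bool)
        mask[:, :15] = True
        r = density_relation(classes, mask, ~mask)
        assert r.dms == 2

    def test_max_auxiliary_output(self):
        r = self.rel(4, 2)
        assert r.dms_max == 4 and (r.cm, r.cs) == (4, 2)

    def test_occurrences_are_simplices(self):
        r = self.rel(3, 1)
        assert r.occurrence_in.sum() == pytest.approx(1.0)
        assert r.occurrence_out.sum() == pytest.approx(1.0)


class TestDescribeDensity:
    @staticmethod
    def plateau_scene(vm, vs, size=96, radius=18):
        from skimage.draw import disk as sk_disk

        img = np.full((size, size), float(vs))
        mask = np.zeros((size, size), bool)
        rr, cc = sk_disk((size // 2, size // 2), radius, shape=mask.shape)
        mask[rr, cc] = True
        img[mask] = vm
        box = BoundingBox(size // 2 - radius - 2, size // 2 - radius - 2,
                          2 * radius + 4, 2 * radius + 4)
        return GrayImage(img.astype(np.uint8), L=255, id="p"), mask, box

    @pytest.mark.parametrize(
        "vm,vs,expected", [(100, 220, 1), (160, 160, 2), (220, 100, 3)]
    )
    def test_rule_coverage_on_noiseless_plateaus(self, vm, vs, expected):
        img, mask, box = self.plateau_scene(vm, vs)
        with pytest.warns(UserWarning):
            d = describe_density(img, mask, box, seed=0)
        assert d["dms_dm"] == expected
        assert d["dms_gray"] == expected  # D1 and D2 agree on two-plateau scenes
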