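import numpy as np
import pytest

from massdesc.phantoms import PhantomSpec, make_mask
from massdesc.shape import analyze_skeleton, describe_shape, shape_features, skeletonize

from conftest import ellipse_mask


def summarize(mask, **kw):
    return analyze_skeleton(skeletonize(mask), mask, **kw)


class TestSkeletonize:
    def test_bar_gives_single_line(self):
        bar = np.zeros((9, 27), bool)
        bar[3:6, 3:24] = True
        skel = skeletonize(bar)
        rows = np.unique(np.nonzero(skel)[0])
        assert len(rows) <= 2  # essentially one horizontal line
        s = summarize(bar)
        assert (s.n_endpoints, s.n_bifurcations) == (2, 0)

    def test_disk_skeleton_is_central_cluster(self, disk_mask):
        skel = skeletonize(disk_mask)
        pts = np.argwhere(skel)
        assert np.abs(pts - 80).max() <= 15  # within a quarter radius of center

    def test_agrees_with_medial_axis_on_plus(self):
        from skimage.morphology import medial_axis

        plus = np.zeros((31, 31), bool)
        plus[13:18, 3:28] = True
        plus[3:28, 13:18] = True
        skel = skeletonize(plus)
        # thinning result lies on (a dilation of) the medial axis
        from skimage.morphology import dilation, disk

        assert np.all(~skel | dilation(medial_axis(plus), disk(2)))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            skeletonize(np.zeros((8, 8), bool))


class TestAnalyzeSkeleton:
    def test_plus_shape_four_endpoints_one_bifurcation(self):
        plus = np.zeros((31, 31), bool)
        plus[13:18, 3:28] = True
        plus[3:28, 13:18] = True
        s = summarize(plus)
        assert (s.n_endpoints, s.n_bifurcations) == (4, 1)

    def test_single_pixel_skeleton(self):
        one = np.zeros((9, 9), bool)
        one[4, 4] = True
        s = summarize(one)
        assert (s.n_endpoints, s.n_bifurcations) == (1, 0)
        assert s.distances.tolist() == [0.0]

    def test_center_is_medial_point_of_bar(self):
        bar = np.zeros((9, 31), bool)
        bar[3:6, 3:28] = True
        s = summarize(bar)
        assert s.center[0] == 4  # middle row of the bar

    def test_endpoint_distances_translation_invariant(self, star_mask):
        p0 = np.sort(summarize(star_mask).distances)
        shifted = np.roll(np.roll(star_mask, 7, axis=0), -5, axis=1)
        assert np.allclose(np.sort(summarize(shifted).distances), p0)

    def test_endpoint_distances_stable_under_rot90(self, star_mask):
        p0 = np.sort(summarize(star_mask).distances)
        p1 = np.sort(summarize(np.rot90(star_mask)).distances)
        assert len(p0) == len(p1)
        assert np.abs(p0 - p1).max() <= 1.5  # thinning is not exactly 90deg-equivariant


class TestShapeFeatures:
    def test_is_identity_on_random_phantoms(self):
        for seed in range(10):
            spec = PhantomSpec(patch_size=96, r0=20,
                               harmonics=((0.1 + 0.01 * seed, 3 + seed % 5, 0.7 * seed),),
                               seed=seed)
            mask, _ = make_mask(spec)
            s = summarize(mask)
            f = shape_features(s)
            assert f.is_ == s.n_endpoints + s.n_bifurcations
            assert f.n_lobes == max(s.n_endpoints - 2, 0)
            assert f.p_var == pytest.approx(f.p_std**2)

    def test_line_skeleton_matches_benign_anchor(self):
        # smooth elongated mass: two endpoints, no bifurcation -> IS=2, 0 lobes
        s = summarize(ellipse_mask(2.0))
        f = shape_features(s)
        assert (s.n_endpoints, s.n_bifurcations, f.is_, f.n_lobes) == (2, 0, 2, 0)

    @pytest.mark.parametrize("aspect", [1.2, 1.5, 2.0, 3.0])
    def test_ellipses_have_zero_lobes(self, aspect):
        assert describe_shape(ellipse_mask(aspect)).n_lobes == 0

    def test_moments_match_scipy_conventions(self):
        from scipy import stats

        p = np.array([3.0, 5.0, 9.0, 11.0, 20.0])
        s = summarize(ellipse_mask(1.5))
        s.distances = p
        f = shape_features(s)
        assert f.p_mean == pytest.approx(p.mean())
        assert f.p_var == pytest.approx(p.var(ddof=1))
        assert f.p_skew == pytest.approx(stats.skew(p, bias=False))
        assert f.p_kurt == pytest.approx(stats.kurtosis(p, fisher=False, bias=False))

    def test_degenerate_distance_set_flagged(self):
        one = np.zeros((9, 9), bool)
        one[4, 4] = True
        f = shape_features(summarize(one))
        assert f.degenerate and f.p_mean == 0.0 and f.p_var == 0.0

    def test_lobes_nondecreasing_in_amplitude(self):
        means = []
        for a in (0.0, 0.05, 0.10, 0.15, 0.20):
            vals = []
            for seed in range(20):
                harmonics = ((a, 6, 0.3 * seed),) if a > 0 else ()
                spec = PhantomSpec(patch_size=160, r0=30 + seed % 5, harmonics=harmonics, seed=seed)
                mask, _ = make_mask(spec)
                vals.append(describe_shape(mask).n_lobes)
            means.append(np.mean(vals))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_star_lobe_count_near_harmonic_order(self):
        # a k-lobed star thins to ~k radial branches: n_lobes = Np - 2 ~ k - 2
        vals = []
        for seed in range(10):
            mask, _ = make_mask(PhantomSpec(patch_size=160, r0=32,
                                            harmonics=((0.22, 6, 0.5 * seed),), seed=seed))
            vals.append(describe_shape(mask).n_lobes)
        assert all(3 <= v <= 6 for v in vals)
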