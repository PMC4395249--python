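import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netscale import (
    FiberSet,
    backbone_bundles,
    bundle_center,
    bundle_scalar_test,
    classify_fibers,
    cross_subject_consistency,
    hausdorff_distance,
    mean_closest_distance,
)
from netscale.bundles import BundleAtlas, per_bundle_scalar_tests, resample_polyline


def straight(y=0.0, z=0.0, n=11, length=10.0):
    x = np.linspace(0.0, length, n)
    return np.column_stack([x, np.full(n, y), np.full(n, z)])


class TestResamplePolyline:
    def test_step_and_endpoints(self):
        f = straight(n=3, length=10.0)
        out = resample_polyline(f, step=1.0)
        assert len(out) == 11
        assert np.allclose(out[0], f[0])
        assert np.allclose(out[-1], f[-1])
        seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.allclose(seg, 1.0)

    def test_degenerate_fiber(self):
        f = np.zeros((4, 3))
        out = resample_polyline(f)
        assert len(out) == 1


class TestFiberDistances:
    def test_parallel_offset_mean_closest_exact(self):
        a = straight(y=0.0)
        b = straight(y=2.5)
        assert mean_closest_distance(a, b) == pytest.approx(2.5, abs=1e-9)

    def test_hausdorff_parallel_offset(self):
        assert hausdorff_distance(straight(), straight(y=3.0)) == pytest.approx(3.0)

    def test_identity_zero(self):
        a = straight()
        assert mean_closest_distance(a, a) == 0.0
        assert hausdorff_distance(a, a) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_hausdorff_dominates_mean_closest(self, seed):
        rng = np.random.default_rng(seed)
        a = np.cumsum(rng.normal(size=(8, 3)), axis=0)
        b = np.cumsum(rng.normal(size=(6, 3)), axis=0) + rng.normal(size=3)
        assert hausdorff_distance(a, b) >= mean_closest_distance(a, b) - 1e-12


class TestBackboneBundles:
    def test_same_block_pairs_only(self):
        labels = np.array([0, 0, 1, 1])  # landmark id i -> labels[i-1]
        assignments = [(1, 2), (3, 4), (1, 3), None]
        atlas = backbone_bundles(assignments, labels, scale=2)
        assert atlas.backbone == {0: [0], 1: [1]}
        assert atlas.scale == 2


class TestClassifyFibers:
    def make_atlas(self):
        fibers = FiberSet(
            [
                straight(y=0.0),  # backbone of bundle 0
                straight(y=20.0),  # backbone of bundle 1
                straight(y=1.0),  # near bundle 0
                straight(y=10.0),  # 9 mm from both: unassigned
            ]
        )
        atlas = BundleAtlas(scale=1, backbone={0: [0], 1: [1]})
        return atlas, fibers

    def test_threshold_respected(self):
        atlas, fibers = self.make_atlas()
        out = classify_fibers(atlas, fibers, threshold=4.0)
        assert out.classified[0] == [2]
        assert out.classified.get(1, []) == []
        assert out.unassigned == [3]
        # contract: every classified fiber is within threshold of its bundle
        for lab, ids in out.classified.items():
            for fid in ids:
                d = min(
                    mean_closest_distance(fibers.fibers[fid], fibers.fibers[m])
                    for m in out.backbone[lab]
                )
                assert d <= 4.0

    def test_tie_goes_to_smaller_label(self):
        fibers = FiberSet([straight(y=0.0), straight(y=10.0), straight(y=5.0)])
        atlas = BundleAtlas(scale=1, backbone={0: [0], 1: [1]})
        out = classify_fibers(atlas, fibers, threshold=6.0)
        assert out.classified[0] == [2]

    def test_idempotent(self):
        atlas, fibers = self.make_atlas()
        once = classify_fibers(atlas, fibers, threshold=4.0)
        twice = classify_fibers(once, fibers, threshold=4.0)
        assert twice.classified == once.classified
        assert twice.unassigned == once.unassigned

    def test_center_linkage(self):
        atlas, fibers = self.make_atlas()
        out = classify_fibers(atlas, fibers, threshold=4.0, linkage="center")
        assert out.classified[0] == [2]
        assert 0 in out.centers and 1 in out.centers

    def test_empty_backbone_rejected(self):
        with pytest.raises(ValueError):
            classify_fibers(BundleAtlas(scale=1), FiberSet([straight()]))


class TestBundleCenter:
    def test_median_line_wins(self):
        polys = [straight(y=0.0), straight(y=1.0), straight(y=5.0)]
        # y=1 has the smallest worst-case Hausdorff distance (4 vs 5)
        assert bundle_center(polys) == 1

    def test_ids_are_returned(self):
        polys = [straight(y=0.0), straight(y=1.0), straight(y=5.0)]
        assert bundle_center(polys, ids=[10, 20, 30]) == 20

    def test_single_member(self):
        assert bundle_center([straight()], ids=[42]) == 42

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bundle_center([])


class TestCrossSubjectConsistency:
    def test_pairwise_hausdorff_mean(self):
        subj1 = {0: straight(y=0.0), 1: straight(y=10.0)}
        subj2 = {0: straight(y=1.0), 1: straight(y=12.0), 2: straight(y=50.0)}
        per_bundle, mean = cross_subject_consistency([subj1, subj2])
        assert set(per_bundle) == {0, 1}  # only common labels
        assert per_bundle[0] == pytest.approx(1.0)
        assert per_bundle[1] == pytest.approx(2.0)
        assert mean == pytest.approx(1.5)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            cross_subject_consistency([{0: straight()}])


class TestBundleScalarTest:
    def test_matches_scipy_welch(self):
        from scipy import stats

        a = [0.41, 0.44, 0.39, 0.45]
        b = [0.50, 0.52, 0.48]
        res = bundle_scalar_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue)
        assert not res.exact_difference

    def test_zero_variance_equal_means(self):
        res = bundle_scalar_test([0.4, 0.4], [0.4, 0.4])
        assert res.pvalue == 1.0 and res.statistic == 0.0

    def test_zero_variance_unequal_means_flagged(self):
        res = bundle_scalar_test([0.5, 0.5], [0.4, 0.4])
        assert res.exact_difference
        assert res.pvalue == 0.0
        assert np.isinf(res.statistic)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            bundle_scalar_test([0.4], [0.5, 0.6])

    def test_per_bundle_tests_common_labels(self):
        out = per_bundle_scalar_tests(
            {0: [0.4, 0.5], 1: [0.3, 0.35]}, {0: [0.6, 0.7], 2: [0.1, 0.2]}
        )
        assert set(out) == {0}
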