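import numpy as np
import pytest

from netscale import (
    NetworkTree,
    build_tree,
    consistency_profile,
    subnetwork_displacement,
    transfer_labels,
)
from netscale.errors import LandmarkMismatchError
from netscale.tree import TreeNode


def hierarchical_distance(n_groups=3, n_per=4, within=0.1, between=1.0, seed=0):
    """Block distance matrix with small within-group, large cross-group values."""
    L = n_groups * n_per
    truth = np.repeat(np.arange(n_groups), n_per)
    rng = np.random.default_rng(seed)
    D = np.where(truth[:, None] == truth[None, :], within, between)
    noise = rng.uniform(0, 0.02, (L, L))
    D = D + 0.5 * (noise + noise.T)
    np.fill_diagonal(D, 0.0)
    return D, truth


class TestBuildTree:
    def test_single_landmark_leaf_tree(self):
        tree = build_tree(np.zeros((1, 1)))
        assert tree.root.is_leaf
        assert tree.n_scales == 1
        assert tree.scale_labels(1).tolist() == [tree.root.node_id]

    def test_recovers_planted_groups(self):
        D, truth = hierarchical_distance()
        tree = build_tree(D, seed=0)
        labels = tree.scale_labels(2)
        # same group <-> same label
        for g in range(3):
            assert len(set(labels[truth == g])) == 1
        assert len(np.unique(labels)) == 3

    def test_scales_are_nested(self):
        D, _ = hierarchical_distance(n_groups=4, n_per=6)
        tree = build_tree(D, seed=1)
        cuts = tree.all_scale_labels()
        for shallow, deep in zip(cuts, cuts[1:]):
            # each deep block lies inside exactly one shallow block
            for b in np.unique(deep):
                assert len(np.unique(shallow[deep == b])) == 1

    def test_min_size_stops_recursion(self):
        D, _ = hierarchical_distance(n_groups=2, n_per=2)
        tree = build_tree(D, min_size=5)
        assert tree.root.is_leaf

    def test_max_depth_stops_recursion(self):
        D, _ = hierarchical_distance()
        tree = build_tree(D, max_depth=1)
        assert tree.root.is_leaf

    def test_deterministic_for_fixed_seed(self):
        D, _ = hierarchical_distance()
        t1 = build_tree(D, seed=7)
        t2 = build_tree(D, seed=7)
        assert t1.to_json() == t2.to_json()


class TestNetworkTree:
    def make_tree(self):
        root = TreeNode(node_id=1, depth=1, landmark_ids=np.arange(1, 5))
        a = TreeNode(node_id=2, depth=2, landmark_ids=np.array([1, 2]))
        b = TreeNode(node_id=3, depth=2, landmark_ids=np.array([3, 4]))
        root.children = [a, b]
        return NetworkTree(root, 4)

    def test_partition_invariant_enforced(self):
        root = TreeNode(node_id=1, depth=1, landmark_ids=np.arange(1, 5))
        root.children = [TreeNode(node_id=2, depth=2, landmark_ids=np.array([1, 2]))]
        with pytest.raises(ValueError, match="partition"):
            NetworkTree(root, 4)
        with pytest.raises(ValueError, match="root"):
            NetworkTree(TreeNode(node_id=1, depth=1, landmark_ids=np.array([1, 2])), 4)

    def test_scale_labels_persist_below_leaves(self):
        tree = self.make_tree()
        assert tree.scale_labels(1).tolist() == [1, 1, 1, 1]
        assert tree.scale_labels(2).tolist() == [2, 2, 3, 3]
        # cutting deeper than the tree keeps the deepest labels
        assert tree.scale_labels(5).tolist() == [2, 2, 3, 3]

    def test_json_round_trip(self):
        tree = self.make_tree()
        again = NetworkTree.from_json(tree.to_json())
        assert again.to_json() == tree.to_json()
        assert again.n_blocks(2) == 2

    def test_newick_topology(self):
        assert self.make_tree().to_newick() == "(1-2,3-4)n1;"


class TestTransferLabels:
    def test_identity_and_permutation(self):
        D, _ = hierarchical_distance()
        tree = build_tree(D, seed=0)
        L = tree.n_landmarks
        ident = transfer_labels(tree, np.arange(1, L + 1))
        assert np.array_equal(ident[2], tree.scale_labels(2))
        perm = np.arange(L, 0, -1)
        flipped = transfer_labels(tree, perm)
        assert np.array_equal(flipped[2], tree.scale_labels(2)[::-1])

    def test_missing_id_named(self):
        D, _ = hierarchical_distance()
        tree = build_tree(D, seed=0)
        ids = [i for i in range(1, tree.n_landmarks + 1) if i != 7]
        with pytest.raises(LandmarkMismatchError, match="7"):
            transfer_labels(tree, ids)


class TestConsistencyProfile:
    def test_scale1_is_overall_mean(self):
        D, _ = hierarchical_distance()
        tree = build_tree(D, seed=0)
        prof = consistency_profile(tree, D, D)
        off = D[~np.eye(len(D), dtype=bool)]
        assert prof.per_scale_mean[0] == pytest.approx(off.mean())

    def test_identical_G_P_reduce_to_G(self):
        D, _ = hierarchical_distance()
        tree = build_tree(D, seed=0)
        p1 = consistency_profile(tree, D, D)
        # 0.5*G + 0.5*P with G == P == D is just D
        p2 = consistency_profile(tree, D, np.zeros_like(D))
        assert np.allclose(p1.per_scale_mean, 2.0 * p2.per_scale_mean)

    def test_planted_hierarchy_curve_non_increasing(self):
        D, _ = hierarchical_distance()
        tree = build_tree(D, seed=0)
        prof = consistency_profile(tree, D, D)
        vals = prof.per_scale_mean[~np.isnan(prof.per_scale_mean)]
        assert np.all(np.diff(vals) <= 1e-12)


class TestSubnetworkDisplacement:
    def test_identical_coordinates_zero(self):
        coords = np.random.default_rng(0).normal(size=(9, 3))
        labels = np.repeat([0, 1, 2], 3)
        per_block, avg = subnetwork_displacement(coords, coords, labels)
        assert avg == 0.0
        assert all(v == 0.0 for v in per_block.values())

    def test_translation_equivariance(self):
        coords = np.random.default_rng(1).normal(size=(12, 3))
        t = np.array([3.0, -4.0, 0.0])  # |t| = 5
        labels = np.repeat([0, 1], 6)
        per_block, avg = subnetwork_displacement(coords, coords + t, labels)
        assert avg == pytest.approx(5.0)
        assert all(v == pytest.approx(5.0) for v in per_block.values())

    def test_three_landmark_block_brute_force(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [10.0, 0, 0]])
        labels = np.zeros(3, dtype=int)
        # representative = member with min mean distance to the others
        means = [
            np.mean([np.linalg.norm(coords[i] - coords[j]) for j in range(3) if j != i])
            for i in range(3)
        ]
        rep = int(np.argmin(means))
        shifted = coords + np.array([0.0, 2.0, 0.0])
        per_block, _ = subnetwork_displacement(coords, shifted, labels)
        assert per_block[0] == pytest.approx(
            np.linalg.norm(coords[rep] - shifted[rep])
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subnetwork_displacement(np.zeros((3, 3)), np.zeros((4, 3)), np.zeros(3))
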