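import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from netscale import (
    UNSPLITTABLE,
    SpectrumScan,
    baseline_split,
    delta_grid,
    eigengap_curves,
    select_scale,
)
from netscale.cluster import _local_extrema, EigengapCurve


def two_cliques_affinity(n_per=4, w=0.8):
    """Two disconnected equal cliques: within-block weight w, diagonal 1."""
    n = 2 * n_per
    W = np.zeros((n, n))
    for b in range(2):
        sl = slice(b * n_per, (b + 1) * n_per)
        W[sl, sl] = w
    np.fill_diagonal(W, 1.0)
    return W


class TestDeltaGrid:
    def test_endpoints_and_count(self):
        D = np.array(
            [
                [0.0, 0.2, 0.5, 0.8],
                [0.2, 0.0, 0.4, 0.6],
                [0.5, 0.4, 0.0, 0.3],
                [0.8, 0.6, 0.3, 0.0],
            ]
        )
        grid = delta_grid(D)
        assert len(grid) == 4
        assert grid[0] == pytest.approx(0.2)
        assert grid[-1] == pytest.approx(0.8)
        assert np.all(np.diff(grid) > 0)

    def test_two_landmarks_constant_grid(self):
        # a 2x2 distance matrix is necessarily constant off-diagonal
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        with pytest.warns(UserWarning, match="constant"):
            grid = delta_grid(D)
        assert grid.tolist() == [0.7]

    def test_constant_matrix_single_point_with_warning(self):
        D = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.warns(UserWarning, match="constant"):
            grid = delta_grid(D)
        assert np.allclose(grid, [1.0])

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            delta_grid(np.zeros((1, 1)))


class TestEigengapCurves:
    def test_two_disconnected_cliques_K2_gap_to_one(self):
        W = two_cliques_affinity(n_per=4, w=0.8)
        curve = eigengap_curves(W, delta=0.5, M_limit=500)
        assert np.all(curve.K == 2)
        assert curve.gap[-1] > 0.999
        assert np.all(np.diff(curve.gap) >= -1e-12)  # monotone to 1

    def test_uniform_complete_graph_stops_at_K1(self):
        W = np.ones((4, 4))
        curve = eigengap_curves(W, delta=0.5)
        # magnitudes {1, 0, 0, 0}: gap at K=1 dominates immediately
        assert len(curve.M) == 1
        assert curve.K[0] == 1

    def test_connected_graph_reaches_K1(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(0.2, 1.0, (6, 6))
        W = 0.5 * (A + A.T)
        np.fill_diagonal(W, 1.0)
        curve = eigengap_curves(W, delta=0.5, M_limit=10_000)
        assert curve.K[-1] == 1

    def test_matches_dense_brute_force(self):
        rng = np.random.default_rng(11)
        A = rng.uniform(0.05, 1.0, (7, 7))
        W = 0.5 * (A + A.T)
        np.fill_diagonal(W, 1.0)
        curve = eigengap_curves(W, delta=1.0, M_limit=200)
        T = W / W.sum(axis=1, keepdims=True)
        mags = np.sort(np.abs(np.linalg.eigvals(T)))[::-1]
        for idx, m in enumerate(curve.M):
            powered = mags**m
            diffs = powered[:-1] - powered[1:]
            assert curve.K[idx] == np.argmax(diffs) + 1
            assert curve.gap[idx] == pytest.approx(diffs.max(), abs=1e-8)


class TestLocalExtrema:
    def test_interior_extrema(self):
        vals = np.array([0.1, 0.5, 0.2, 0.7, 0.3])
        maxima, minima = _local_extrema(vals)
        assert 1 in maxima and 3 in maxima
        assert 2 in minima

    def test_plateau_uses_leftmost_index(self):
        vals = np.array([0.1, 0.5, 0.5, 0.5, 0.1])
        maxima, _ = _local_extrema(vals)
        assert maxima == [1]

    def test_constant_curve_has_no_extrema(self):
        maxima, minima = _local_extrema(np.full(10, 0.4))
        assert maxima == [] and minima == []

    def test_boundaries_qualify(self):
        maxima, minima = _local_extrema(np.array([0.9, 0.5, 0.1]))
        assert maxima == [0]
        assert minima == [2]


class TestSelectScale:
    def test_single_delta_interior_max(self):
        curve = EigengapCurve(
            delta=0.4,
            eigenvalue_magnitudes=np.array([1.0, 0.5]),
            M=np.arange(1, 8),
            gap=np.array([0.1, 0.3, 0.6, 0.4, 0.2, 0.1, 0.05]),
            K=np.array([3, 3, 3, 2, 2, 1, 1]),
        )
        scan = SpectrumScan([curve])
        choice = select_scale(scan)
        assert choice.delta == 0.4
        assert choice.K == 3
        assert choice.M == 3
        # bracketed by the scan ends (no interior minima before/after peak)
        assert choice.M_a == 1 and choice.M_b == 7

    def test_stability_wins_and_ties_go_to_larger_delta(self):
        def curve(delta, peak_at, length):
            gap = np.concatenate(
                [np.linspace(0.1, 0.9, peak_at), np.linspace(0.9, 0.1, length - peak_at)]
            )
            K = np.full(length, 2)
            K[-1] = 1
            return EigengapCurve(delta, np.array([1.0]), np.arange(1, length + 1), gap, K)

        wide = curve(0.3, 5, 50)
        narrow = curve(0.9, 3, 10)
        assert select_scale(SpectrumScan([wide, narrow])).delta == 0.3
        twin = curve(0.5, 5, 50)
        assert select_scale(SpectrumScan([wide, twin])).delta == 0.5

    def test_flat_scan_unsplittable(self):
        flat = EigengapCurve(
            delta=0.5,
            eigenvalue_magnitudes=np.array([1.0, 1.0]),
            M=np.arange(1, 20),
            gap=np.full(19, 0.7),
            K=np.full(19, 2),
        )
        assert select_scale(SpectrumScan([flat])) is UNSPLITTABLE

    def test_censored_flag_reported(self):
        W = two_cliques_affinity()
        curve = eigengap_curves(W, delta=0.5, M_limit=200)
        choice = select_scale(SpectrumScan([curve]))
        assert choice.K == 2
        assert choice.censored  # K never reached 1 before the cap


class TestBaselineSplit:
    def test_disconnected_cliques_exact_membership(self):
        W = two_cliques_affinity(n_per=4, w=0.9)
        labels = baseline_split(W, 2, seed=0)
        assert set(labels) == {0, 1}
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        assert labels[0] == 0  # canonical: first appearance gets label 0

    def test_K_equal_L_rejected(self):
        W = np.ones((4, 4))
        with pytest.raises(ValueError):
            baseline_split(W, 4)
        with pytest.raises(ValueError):
            baseline_split(W, 1)

    def test_planted_three_blocks_recovered(self):
        # in-block affinity 0.9, cross 0.1, 8 nodes per block, 50 seeds
        truth = np.repeat([0, 1, 2], 8)
        good = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            W = np.where(truth[:, None] == truth[None, :], 0.9, 0.1)
            W = W + rng.uniform(-0.02, 0.02, W.shape)
            W = 0.5 * (W + W.T)
            np.fill_diagonal(W, 1.0)
            labels = baseline_split(W, 3, seed=seed)
            if adjusted_rand_score(truth, labels) >= 0.95:
                good += 1
        assert good >= 48
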