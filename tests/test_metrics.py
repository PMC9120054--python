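import itertools

import networkx as nx
import numpy as np
import pytest

from connstat.metrics import (
    MetricCurve,
    SparsityGrid,
    auc_over_thresholds,
    betweenness,
    clustering_coefficient,
    metric_curves,
    node_strength,
    threshold_proportional,
)
from tests.conftest import random_symmetric_matrix

# ---------------------------------------------------------------- oracles


def brute_strength(W):
    n = len(W)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += W[i, j]
    return out


def brute_betweenness(W):
    """Exhaustive simple-path enumeration with fractional credit for ties.

    Each unordered source-target pair contributes once; path length is the
    sum of 1/w over the path's edges.
    """
    n = len(W)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = []

        def dfs(node, visited, length):
            if node == t:
                paths.append((length, tuple(visited)))
                return
            for u in range(n):
                if W[node, u] > 0 and u not in visited:
                    dfs(u, visited + [u], length + 1.0 / W[node, u])

        dfs(s, [s], 0.0)
        if not paths:
            continue
        best = min(length for length, _ in paths)
        minimal = [p for length, p in paths if length <= best * (1 + 1e-12)]
        for p in minimal:
            for node in p[1:-1]:
                bc[node] += 1.0 / len(minimal)
    return bc


def brute_clustering(W):
    n = len(W)
    mx = W.max()
    if mx == 0:
        return np.zeros(n)
    What = W / mx
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if W[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                total += (What[i, j] * What[i, h] * What[j, h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def brute_threshold_edges(W, S):
    """Top-k upper-triangle edges by exhaustive sort with the index tie-break."""
    n = len(W)
    k = int(np.floor(S * n * (n - 1) / 2))
    edges = [(i, j, W[i, j]) for i in range(n) for j in range(i + 1, n)]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    return {(i, j) for i, j, w in edges[:k] if w > 0}


def nx_graph(W):
    G = nx.Graph()
    G.add_nodes_from(range(len(W)))
    for i in range(len(W)):
        for j in range(i + 1, len(W)):
            if W[i, j] > 0:
                G.add_edge(i, j, weight=W[i, j], length=1.0 / W[i, j])
    return G


# ---------------------------------------------------------------- grids


class TestSparsityGrid:
    def test_default_grid(self):
        g = SparsityGrid.default()
        assert len(g) == 21
        assert g.values[0] == pytest.approx(0.10)
        assert g.values[-1] == pytest.approx(0.30)
        np.testing.assert_allclose(np.diff(g.values), 0.01)

    def test_from_spec_matches_default(self):
        np.testing.assert_allclose(SparsityGrid.from_spec("0.10:0.30:0.01").values,
                                   SparsityGrid.default().values)

    @pytest.mark.parametrize("bad", [[0.0, 0.1], [0.1, 0.1], [0.2, 0.1], [1.5], []])
    def test_invalid_grids_rejected(self, bad):
        with pytest.raises(ValueError):
            SparsityGrid(np.array(bad))


# ---------------------------------------------------------------- thresholding


class TestThresholdProportional:
    def test_top1_selection(self, make_matrix):
        W = np.array([[0, 3.0, 2.0], [3.0, 0, 1.0], [2.0, 1.0, 0]])
        out = threshold_proportional(make_matrix(W), 1 / 3).weights
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 3.0
        np.testing.assert_array_equal(out, expected)

    def test_s_equal_one_is_identity(self, random_matrix):
        m = random_matrix(8)
        out = threshold_proportional(m, 1.0)
        np.testing.assert_array_equal(out.weights, m.weights)

    def test_matches_sort_oracle_10_nodes(self, rng, make_matrix):
        W = random_symmetric_matrix(10, rng)
        out = threshold_proportional(make_matrix(W), 0.20).weights
        kept = {(i, j) for i in range(10) for j in range(i + 1, 10) if out[i, j] > 0}
        assert len(kept) == int(np.floor(0.20 * 45)) == 9
        assert kept == brute_threshold_edges(W, 0.20)

    def test_weights_preserved_not_binarized(self, rng, make_matrix):
        W = random_symmetric_matrix(6, rng)
        out = threshold_proportional(make_matrix(W), 0.5).weights
        nz = out > 0
        np.testing.assert_array_equal(out[nz], W[nz])

    def test_tie_break_by_index(self, make_matrix):
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 2), (2, 3)]:
            W[i, j] = W[j, i] = 5.0  # all tied
        out = threshold_proportional(make_matrix(W), 2 / 6).weights
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4) if out[i, j] > 0}
        assert kept == {(0, 1), (0, 2)}

    def test_sparse_matrix_keeps_all_with_warning(self, make_matrix, caplog):
        W = np.zeros((6, 6))
        W[0, 1] = W[1, 0] = 2.0
        with caplog.at_level("WARNING", logger="connstat.metrics"):
            out = threshold_proportional(make_matrix(W), 0.9)
        np.testing.assert_array_equal(out.weights, W)
        assert "density below requested sparsity" in caplog.text

    @pytest.mark.parametrize("S", [0.0, -0.1, 1.5])
    def test_invalid_s_rejected(self, random_matrix, S):
        with pytest.raises(ValueError, match="sparsity"):
            threshold_proportional(random_matrix(5), S)

    def test_idempotent(self, random_matrix):
        m = random_matrix(12)
        once = threshold_proportional(m, 0.25)
        twice = threshold_proportional(once, 0.25)
        np.testing.assert_array_equal(once.weights, twice.weights)

    def test_monotone_nested_edge_sets(self, random_matrix):
        m = random_matrix(12)
        prev = None
        for S in (0.10, 0.20, 0.30, 0.50):
            out = threshold_proportional(m, S).weights
            kept = {(i, j) for i in range(12) for j in range(i + 1, 12) if out[i, j] > 0}
            if prev is not None:
                assert prev <= kept
            prev = kept


# ---------------------------------------------------------------- centralities


class TestNodeStrength:
    def test_regular_graph(self, make_matrix):
        W = np.ones((4, 4)) - np.eye(4)
        np.testing.assert_array_equal(node_strength(make_matrix(W)), [3, 3, 3, 3])

    def test_empty_graph(self, make_matrix):
        np.testing.assert_array_equal(node_strength(make_matrix(np.zeros((5, 5)))), np.zeros(5))

    def test_matches_brute_force(self, rng, make_matrix):
        W = random_symmetric_matrix(8, rng)
        np.testing.assert_allclose(node_strength(make_matrix(W)), brute_strength(W), rtol=1e-12)


class TestBetweenness:
    def test_path_graph(self, make_matrix):
        W = np.array([[0, 1.0, 0], [1.0, 0, 1.0], [0, 1.0, 0]])
        np.testing.assert_allclose(betweenness(make_matrix(W)), [0, 1, 0])

    def test_star_graph(self, make_matrix):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        bc = betweenness(make_matrix(W))
        assert bc[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_fractional_credit_on_tied_paths(self, make_matrix):
        # diamond: two equal-length shortest paths 0-1-3 and 0-2-3
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            W[i, j] = W[j, i] = 1.0
        bc = betweenness(make_matrix(W))
        np.testing.assert_allclose(bc, [0.5, 0.5, 0.5, 0.5])

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_path_enumeration_oracle(self, seed, make_matrix):
        rng = np.random.default_rng(seed)
        W = random_symmetric_matrix(7, rng, density=0.7)
        np.testing.assert_allclose(
            betweenness(make_matrix(W)), brute_betweenness(W), atol=1e-10
        )

    def test_disconnected_pairs_contribute_zero(self, make_matrix):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        np.testing.assert_allclose(betweenness(make_matrix(W)), np.zeros(5))

    def test_all_zero_matrix_rejected(self, make_matrix):
        with pytest.raises(ValueError, match="all-zero"):
            betweenness(make_matrix(np.zeros((4, 4))))


class TestClusteringCoefficient:
    def test_binary_triangle(self, make_matrix):
        W = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(clustering_coefficient(make_matrix(W)), 1.0)

    def test_star_graph_no_triangles(self, make_matrix):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 3.0
        np.testing.assert_allclose(clustering_coefficient(make_matrix(W)), 0.0)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_triple_loop_oracle(self, seed, make_matrix):
        rng = np.random.default_rng(seed)
        W = random_symmetric_matrix(8, rng, density=0.6)
        np.testing.assert_allclose(
            clustering_coefficient(make_matrix(W)), brute_clustering(W), atol=1e-10
        )

    def test_binary_graph_equals_triangle_fraction(self, rng, make_matrix):
        W = (random_symmetric_matrix(10, rng, density=0.5) > 0).astype(float)
        C = clustering_coefficient(make_matrix(W))
        A = W
        triangles = np.diag(A @ A @ A) / 2.0
        k = A.sum(axis=1)
        expected = np.where(k > 1, 2.0 * triangles / (k * (k - 1)), 0.0)
        np.testing.assert_allclose(C, expected, atol=1e-12)

    def test_values_in_unit_interval(self, rng, make_matrix):
        for _ in range(5):
            W = random_symmetric_matrix(9, rng, density=0.7)
            C = clustering_coefficient(make_matrix(W))
            assert np.all((C >= 0) & (C <= 1 + 1e-12))


class TestToolboxEquivalence:
    """Published reference implementations (networkx) on random 20-node graphs."""

    @pytest.mark.parametrize("seed", [101, 102, 103, 104, 105])
    def test_strength_exact(self, seed, make_matrix):
        W = random_symmetric_matrix(20, np.random.default_rng(seed))
        G = nx_graph(W)
        expected = np.array([G.degree(i, weight="weight") for i in range(20)])
        # summation order differs between implementations; exact up to float reordering
        np.testing.assert_allclose(node_strength(make_matrix(W)), expected, rtol=1e-13)

    @pytest.mark.parametrize("seed", [101, 102, 103, 104, 105])
    def test_betweenness_matches_networkx(self, seed, make_matrix):
        W = random_symmetric_matrix(20, np.random.default_rng(seed), density=0.4)
        G = nx_graph(W)
        expected = nx.betweenness_centrality(G, weight="length", normalized=False)
        np.testing.assert_allclose(
            betweenness(make_matrix(W)), [expected[i] for i in range(20)], atol=1e-10
        )

    @pytest.mark.parametrize("seed", [101, 102, 103, 104, 105])
    def test_clustering_matches_networkx(self, seed, make_matrix):
        W = random_symmetric_matrix(20, np.random.default_rng(seed), density=0.4)
        G = nx_graph(W)
        expected = nx.clustering(G, weight="weight")
        np.testing.assert_allclose(
            clustering_coefficient(make_matrix(W)), [expected[i] for i in range(20)], atol=1e-10
        )


# ---------------------------------------------------------------- properties


class TestMetricProperties:
    def test_permutation_equivariance(self, rng, make_matrix):
        W = random_symmetric_matrix(9, rng, density=0.6)
        perm = rng.permutation(9)
        Wp = W[np.ix_(perm, perm)]
        for fn in (node_strength, betweenness, clustering_coefficient):
            np.testing.assert_allclose(fn(make_matrix(Wp)), fn(make_matrix(W))[perm], atol=1e-10)

    def test_scale_behavior(self, rng, make_matrix):
        W = random_symmetric_matrix(9, rng, density=0.6)
        c = 3.7
        np.testing.assert_allclose(
            node_strength(make_matrix(c * W)), c * node_strength(make_matrix(W)), rtol=1e-12
        )
        # betweenness: shortest-path structure unchanged under common scaling
        np.testing.assert_allclose(
            betweenness(make_matrix(c * W)), betweenness(make_matrix(W)), atol=1e-10
        )
        # clustering invariant under scaling due to max-normalization
        np.testing.assert_allclose(
            clustering_coefficient(make_matrix(c * W)),
            clustering_coefficient(make_matrix(W)),
            atol=1e-12,
        )

    def test_strength_monotone_in_sparsity(self, random_matrix):
        m = random_matrix(12)
        prev = None
        for S in (0.1, 0.2, 0.3, 0.6, 1.0):
            s = node_strength(threshold_proportional(m, S))
            if prev is not None:
                assert np.all(s >= prev - 1e-12)
            prev = s


# ---------------------------------------------------------------- curves & AUC


class TestMetricCurves:
    def test_single_point_grid_consistency(self, random_matrix):
        m = random_matrix(10)
        grid = SparsityGrid(np.array([0.25]))
        curves = metric_curves(m, grid)
        Wt = threshold_proportional(m, 0.25)
        np.testing.assert_array_equal(curves["strength"].values[:, 0], node_strength(Wt))
        np.testing.assert_allclose(curves["clustering"].values[:, 0], clustering_coefficient(Wt))

    def test_columns_match_per_threshold_recomputation(self, random_matrix):
        m = random_matrix(10)
        grid = SparsityGrid.default()
        curves = metric_curves(m, grid, metrics=("strength", "clustering"))
        for j, S in enumerate(grid.values):
            Wt = threshold_proportional(m, S)
            np.testing.assert_array_equal(curves["strength"].values[:, j], node_strength(Wt))
            np.testing.assert_allclose(
                curves["clustering"].values[:, j], clustering_coefficient(Wt), atol=1e-12
            )

    def test_strength_curve_constant_once_saturated(self, make_matrix):
        # only 4 nonzero edges: every grid point requests more, so columns agree
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (2, 3), (4, 5)]:
            W[i, j] = W[j, i] = 2.0
        grid = SparsityGrid(np.array([0.5, 0.8, 1.0]))
        curves = metric_curves(make_matrix(W), grid, metrics=("strength",))
        for j in range(1, 3):
            np.testing.assert_array_equal(curves["strength"].values[:, 0], curves["strength"].values[:, j])


class TestAucOverThresholds:
    def test_constant_curve(self):
        grid = SparsityGrid.default()
        c = 4.2
        curve = MetricCurve(np.full((3, 21), c), "strength")
        np.testing.assert_allclose(auc_over_thresholds(curve, grid), 0.20 * c, rtol=1e-12)

    def test_linear_curve_closed_form(self):
        grid = SparsityGrid.default()
        curve = MetricCurve(np.tile(grid.values, (2, 1)), "strength")
        np.testing.assert_allclose(auc_over_thresholds(curve, grid), 0.04, rtol=1e-12)

    def test_matches_refined_piecewise_linear_integration(self, rng):
        grid = SparsityGrid.default()
        vals = rng.uniform(0, 5, size=(4, 21))
        curve = MetricCurve(vals, "strength")
        auc = auc_over_thresholds(curve, grid)
        fine = np.linspace(0.10, 0.30, 20001)
        expected = [np.trapezoid(np.interp(fine, grid.values, v), fine) for v in vals]
        np.testing.assert_allclose(auc, expected, rtol=1e-6)

    def test_single_point_grid_rejected(self):
        grid = SparsityGrid(np.array([0.2]))
        curve = MetricCurve(np.ones((2, 1)), "strength")
        with pytest.raises(ValueError, match="at least 2"):
            auc_over_thresholds(curve, grid)
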