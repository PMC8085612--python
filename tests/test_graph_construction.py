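"""Graph constructions against hand calculations and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphcls import (
    build_cknn,
    build_knn,
    build_mknn,
    build_rmst,
    edge_density,
    minimum_spanning_tree,
    pairwise_euclidean,
)
from graphcls.graph_construction import (
    is_connected,
    gamma_grid,
    k_grid,
    kth_neighbor_distance,
    read_graph,
    write_graph,
)


def edges_of(A):
    return set(map(tuple, np.transpose(np.nonzero(np.triu(A, 1)))))


def random_distance_matrix(rng, n):
    X = rng.normal(size=(n, 3))
    return pairwise_euclidean(X)


# ---------------------------------------------------------------- oracles

def oracle_mst_bruteforce(D):
    """Minimal spanning-tree weight by enumerating all edge subsets (N<=6)."""
    n = len(D)
    pairs = list(itertools.combinations(range(n), 2))
    best = np.inf
    for tree in itertools.combinations(pairs, n - 1):
        A = np.zeros((n, n))
        for u, v in tree:
            A[u, v] = A[v, u] = 1
        if is_connected(A):
            best = min(best, sum(D[u, v] for u, v in tree))
    return best


def oracle_construction(D, method, param, k=1, delta=1.0):
    """Direct evaluation of each construction's defining inequality."""
    n = len(D)
    thr = np.sort(D + np.diag([np.inf] * n), axis=1)
    mst = minimum_spanning_tree(D)
    edges = set(map(tuple, np.sort(mst.edges, axis=1)))
    for i, j in itertools.combinations(range(n), 2):
        d = D[i, j]
        if method == "knn":
            ok = d <= thr[i, param - 1] or d <= thr[j, param - 1]
        elif method == "mknn":
            ok = d <= thr[i, param - 1] and d <= thr[j, param - 1]
        elif method == "cknn":
            ok = d < delta * np.sqrt(thr[i, param - 1] * thr[j, param - 1])
        elif method == "rmst":
            bound = mst.max_edge_on_path[i, j] + param * (
                thr[i, k - 1] + thr[j, k - 1])
            ok = d < bound
        if ok:
            edges.add((i, j))
    return edges


# ------------------------------------------------------------ hand values

class TestLineFixture:
    """1-D points (0, 1, 3, 10): every construction evaluated by hand."""

    def test_distances(self, line_D):
        assert line_D[0, 1] == 1 and line_D[0, 2] == 3 and line_D[0, 3] == 10
        assert line_D[1, 2] == 2 and line_D[1, 3] == 9 and line_D[2, 3] == 7
        np.testing.assert_array_equal(np.diag(line_D), 0)

    def test_mst(self, line_D):
        mst = minimum_spanning_tree(line_D)
        assert edges_of(mst.adjacency()) == {(0, 1), (1, 2), (2, 3)}
        assert mst.total_weight == 10
        assert mst.max_edge_on_path[0, 3] == 7

    def test_knn_k1_equals_mst(self, line_D):
        assert edges_of(build_knn(line_D, 1)) == {(0, 1), (1, 2), (2, 3)}

    def test_mknn_k1_heuristic_is_single_edge(self, line_D):
        # only (0,1) is mutual; the MST union restores connectivity
        thr = kth_neighbor_distance(line_D, 1)
        heur = (line_D <= thr[:, None]) & (line_D <= thr[None, :])
        np.fill_diagonal(heur, False)
        assert edges_of(heur) == {(0, 1)}
        assert edges_of(build_mknn(line_D, 1)) == {(0, 1), (1, 2), (2, 3)}

    def test_cknn_k1_heuristic_empty(self, line_D):
        # 1 < sqrt(1), 2 < sqrt(2), 7 < sqrt(14) are all false
        assert edges_of(build_cknn(line_D, 1)) == {(0, 1), (1, 2), (2, 3)}

    def test_rmst_gamma0_is_mst(self, line_D):
        assert edges_of(build_rmst(line_D, 0.0)) == {(0, 1), (1, 2), (2, 3)}

    def test_rmst_gamma1_complete(self, line_D):
        # (0,2): 3 < 2+3; (1,3): 9 < 7+8; (0,3): 10 < 7+8
        assert edge_density(build_rmst(line_D, 1.0)) == 1.0

    def test_density_values(self, line_D):
        mst = minimum_spanning_tree(line_D)
        assert edge_density(mst.adjacency()) == 0.5  # 3 of 6 pairs


class TestTrivialCases:
    def test_two_points(self):
        D = pairwise_euclidean([[0.0], [2.0]])
        mst = minimum_spanning_tree(D)
        assert edges_of(mst.adjacency()) == {(0, 1)}

    def test_345_triangle(self):
        D = pairwise_euclidean([[0.0, 0.0], [3.0, 4.0]])
        assert D[0, 1] == 5.0

    def test_knn_max_k_complete(self):
        rng = np.random.default_rng(0)
        D = random_distance_matrix(rng, 8)
        assert edge_density(build_knn(D, 7)) == 1.0
        assert edge_density(build_mknn(D, 7)) == 1.0

    def test_cknn_large_delta_complete(self):
        rng = np.random.default_rng(1)
        D = random_distance_matrix(rng, 8)
        assert edge_density(build_cknn(D, 2, delta=1e6)) == 1.0

    def test_k_out_of_range(self, line_D):
        with pytest.raises(ValueError):
            build_knn(line_D, 4)

    def test_cknn_duplicate_points_rejected(self):
        D = pairwise_euclidean([[0.0], [0.0], [5.0]])
        with pytest.raises(ValueError, match="duplicate"):
            build_cknn(D, 1)


# --------------------------------------------------------- oracle equality

@pytest.mark.parametrize("method", ["knn", "mknn", "cknn", "rmst"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_constructions_equal_bruteforce(method, seed):
    """Each edge set equals direct evaluation of its inequality (N <= 7)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 8))
    D = random_distance_matrix(rng, n)
    if method == "rmst":
        for gamma in (0.0, 0.3, 1.5):
            got = edges_of(build_rmst(D, gamma))
            assert got == oracle_construction(D, "rmst", gamma)
    else:
        build = {"knn": build_knn, "mknn": build_mknn, "cknn": build_cknn}[method]
        for k in range(1, n):
            got = edges_of(build(D, k))
            assert got == oracle_construction(D, method, k)


@pytest.mark.parametrize("seed", range(4))
def test_mst_total_weight_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    D = random_distance_matrix(rng, 6)
    mst = minimum_spanning_tree(D)
    assert mst.total_weight == pytest.approx(oracle_mst_bruteforce(D), rel=1e-12)


def test_mst_weight_invariant_under_ties():
    # four corners of a square: many equal-weight spanning trees
    D = pairwise_euclidean([[0, 0], [1, 0], [1, 1], [0, 1]])
    mst = minimum_spanning_tree(D)
    assert mst.total_weight == pytest.approx(3.0)
    assert is_connected(mst.adjacency())


def test_mst_path_max_dominates_tree_edges():
    rng = np.random.default_rng(3)
    D = random_distance_matrix(rng, 10)
    mst = minimum_spanning_tree(D)
    M = mst.max_edge_on_path
    np.testing.assert_allclose(M, M.T)
    np.testing.assert_array_equal(np.diag(M), 0)
    for (u, v), w in zip(mst.edges, mst.weights):
        assert M[u, v] == pytest.approx(w)
    off = ~np.eye(len(M), dtype=bool)
    assert np.all(M[off] >= mst.weights.min() - 1e-15)


# ------------------------------------------------------------- properties

@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.integers(5, 12))
def test_nesting_connectivity_and_degree_bound(seed, n):
    rng = np.random.default_rng(seed)
    D = random_distance_matrix(rng, n)
    thr_cache = {}
    for k in range(1, n):
        knn, mknn = build_knn(D, k), build_mknn(D, k)
        assert edges_of(mknn) <= edges_of(knn)  # "and" implies "or"
        for A in (knn, mknn):
            assert is_connected(A)
            np.testing.assert_array_equal(A, A.T)
            np.testing.assert_array_equal(np.diag(A), 0)
        # pre-union mutual graph bounds every degree by k
        thr = thr_cache.setdefault(k, kth_neighbor_distance(D, k))
        heur = (D <= thr[:, None]) & (D <= thr[None, :])
        np.fill_diagonal(heur, False)
        assert heur.sum(axis=1).max() <= k


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_cknn_monotone_in_k_and_rmst_monotone_in_gamma(seed):
    rng = np.random.default_rng(seed)
    D = random_distance_matrix(rng, 9)
    prev = set()
    for k in range(1, 9):
        cur = edges_of(build_cknn(D, k))
        assert prev <= cur
        prev = cur
    prev = set()
    for gamma in (0.0, 0.1, 0.5, 2.0, 10.0):
        cur = edges_of(build_rmst(D, gamma))
        assert prev <= cur
        prev = cur


def test_density_of_mst_union_graph_is_two_over_n():
    rng = np.random.default_rng(9)
    for n in (5, 10, 20):
        D = random_distance_matrix(rng, n)
        mst = minimum_spanning_tree(D)
        assert edge_density(mst.adjacency()) == pytest.approx(2.0 / n)


def test_grids_are_deduplicated_and_log_spaced():
    ks = k_grid(100, 50)
    assert ks[0] == 1 and ks[-1] == 99
    assert np.all(np.diff(ks) > 0)
    gs = gamma_grid(50)
    assert gs[0] == pytest.approx(1e-3) and gs[-1] == pytest.approx(10.0)


def test_graph_io_roundtrip(tmp_path, line_D):
    A = build_knn(line_D, 2)
    for name in ("g.mtx", "g.tsv"):
        path = tmp_path / name
        write_graph(A, path)
        np.testing.assert_array_equal(read_graph(path, n_nodes=4), A)
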