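"""Geometric graph constructions anchored on the minimum spanning tree.

All four constructions start from the Euclidean distance matrix ``D`` of
the (L1-normalized) feature vectors.  Kruskal's algorithm gives the MST,
whose edges are always retained so that every graph is connected; a
density criterion then adds edges:

* kNN     — edge when *either* endpoint is within the other's ``k``
  nearest neighbors: ``d(i,j) <= d(i, i_k)`` **or** ``d(i,j) <= d(j, j_k)``.
* MkNN    — mutual variant (**and** instead of **or**); the pre-union
  heuristic graph has maximum degree ``k``, suppressing hubs.
* CkNN    — continuous kNN: ``d(i,j) < delta * sqrt(d(i, i_k) * d(j, j_k))``,
  which adapts the neighborhood scale to the local sampling density.
* RMST    — relaxed MST: ``d(i,j) < max-edge-on-MST-path(i,j)
  + gamma * (d(i, i_k) + d(j, j_k))`` with ``k = 1``; a direct edge is kept
  when it is competitive with the bottleneck of the MST path.

Edge weights are discarded after construction: the returned adjacency
matrices are symmetric, hollow 0/1 arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform


def pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    """Full Euclidean distance matrix ``D_ij = ||X_i - X_j||_2``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an N x F matrix")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    D = squareform(pdist(X, metric="euclidean"))
    return D


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")
    return D


@dataclass
class MSTStructure:
    """A minimum spanning tree and its bottleneck-distance matrix.

    ``max_edge_on_path[i, j]`` is the largest edge weight on the unique
    tree path between ``i`` and ``j`` (computed lazily: it costs O(N^2)).
    """

    edges: np.ndarray          # (N-1, 2) int array, each row (u, v) with u < v
    weights: np.ndarray        # (N-1,) edge distances
    n_nodes: int

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes))
        A[self.edges[:, 0], self.edges[:, 1]] = 1.0
        A[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return A

    @cached_property
    def max_edge_on_path(self) -> np.ndarray:
        n = self.n_nodes
        neighbors: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for (u, v), w in zip(self.edges, self.weights):
            neighbors[u].append((int(v), float(w)))
            neighbors[v].append((int(u), float(w)))
        out = np.zeros((n, n))
        for root in range(n):
            # DFS carrying the running path maximum
            stack = [(root, 0.0)]
            seen = np.zeros(n, dtype=bool)
            seen[root] = True
            while stack:
                node, best = stack.pop()
                for nxt, w in neighbors[node]:
                    if not seen[nxt]:
                        seen[nxt] = True
                        m = best if best > w else w
                        out[root, nxt] = m
                        stack.append((nxt, m))
        return out


def minimum_spanning_tree(D: np.ndarray) -> MSTStructure:
    """Kruskal MST of the complete graph weighted by ``D``.

    Ties in edge weight are broken by ascending ``(i, j)`` so the edge set
    is deterministic; the total weight is invariant to the tie-break.
    """
    D = _check_distance_matrix(D)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    iu, ju = np.triu_indices(n, k=1)
    w = D[iu, ju]
    order = np.lexsort((ju, iu, w))  # weight, then (i, j)

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = np.empty((n - 1, 2), dtype=int)
    weights = np.empty(n - 1)
    m = 0
    for idx in order:
        u, v = int(iu[idx]), int(ju[idx])
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            edges[m] = (u, v)
            weights[m] = w[idx]
            m += 1
            if m == n - 1:
                break
    if m != n - 1:
        raise RuntimeError("failed to span all nodes")  # pragma: no cover
    return MSTStructure(edges=edges, weights=weights, n_nodes=n)


def kth_neighbor_distance(D: np.ndarray, k: int) -> np.ndarray:
    """Distance from each sample to its k-th nearest neighbor (self excluded)."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"require 1 <= k < N, got k={k}, N={n}")
    masked = D + np.diag(np.full(n, np.inf))
    return np.sort(masked, axis=1)[:, k - 1]


def _finalize(heur: np.ndarray, mst: MSTStructure) -> np.ndarray:
    A = heur.astype(float)
    np.fill_diagonal(A, 0.0)
    A = np.maximum(A, A.T)
    A = np.maximum(A, mst.adjacency())
    return A


def build_knn(
    D: np.ndarray, k: int, mst: MSTStructure | None = None
) -> np.ndarray:
    """kNN graph union the MST: edge when either endpoint ranks the other
    within its ``k`` nearest neighbors."""
    D = _check_distance_matrix(D)
    mst = mst if mst is not None else minimum_spanning_tree(D)
    thr = kth_neighbor_distance(D, k)
    heur = (D <= thr[:, None]) | (D <= thr[None, :])
    return _finalize(heur, mst)


def build_mknn(
    D: np.ndarray, k: int, mst: MSTStructure | None = None
) -> np.ndarray:
    """Mutual kNN graph union the MST: both endpoints must rank each other
    within their ``k`` nearest neighbors (pre-union degrees are <= k)."""
    D = _check_distance_matrix(D)
    mst = mst if mst is not None else minimum_spanning_tree(D)
    thr = kth_neighbor_distance(D, k)
    heur = (D <= thr[:, None]) & (D <= thr[None, :])
    return _finalize(heur, mst)


def build_cknn(
    D: np.ndarray,
    k: int,
    delta: float = 1.0,
    mst: MSTStructure | None = None,
    literal_product: bool = False,
) -> np.ndarray:
    """Continuous kNN graph union the MST.

    The criterion is ``d(i,j) < delta * sqrt(d(i, i_k) * d(j, j_k))`` —
    the geometric mean of the endpoints' k-th-neighbor distances sets a
    density-adaptive scale.  ``literal_product=True`` switches to the raw
    product ``delta * d(i, i_k) * d(j, j_k)`` for auditing.

    Raises
    ------
    ValueError
        If any sample's k-th-neighbor distance is zero (duplicate points);
        deduplicate or jitter the features first.
    """
    D = _check_distance_matrix(D)
    if delta <= 0:
        raise ValueError("delta must be positive")
    mst = mst if mst is not None else minimum_spanning_tree(D)
    thr = kth_neighbor_distance(D, k)
    if np.any(thr == 0):
        bad = np.flatnonzero(thr == 0)
        raise ValueError(
            f"zero k-th-neighbor distance at samples {bad.tolist()[:10]}: "
            "duplicate points break the CkNN scale; deduplicate or jitter"
        )
    if literal_product:
        scale = delta * thr[:, None] * thr[None, :]
    else:
        scale = delta * np.sqrt(thr[:, None] * thr[None, :])
    heur = D < scale
    return _finalize(heur, mst)


def build_rmst(
    D: np.ndarray,
    gamma: float,
    k: int = 1,
    mst: MSTStructure | None = None,
) -> np.ndarray:
    """Relaxed-MST graph union the MST.

    A direct edge (i, j) is added when
    ``d(i,j) < max_edge_on_MST_path(i,j) + gamma * (d(i,i_k) + d(j,j_k))``,
    i.e. when the direct distance is competitive with the bottleneck of the
    tree path, relaxed by a local-density term.  ``k`` defaults to 1.
    """
    D = _check_distance_matrix(D)
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    mst = mst if mst is not None else minimum_spanning_tree(D)
    thr = kth_neighbor_distance(D, k)
    bound = mst.max_edge_on_path + gamma * (thr[:, None] + thr[None, :])
    heur = D < bound
    return _finalize(heur, mst)


def edge_density(A: np.ndarray) -> float:
    """Fraction of realized undirected edges, ``2|E| / (N (N-1))``."""
    A = np.asarray(A)
    n = A.shape[0]
    if n < 2:
        return 0.0
    return float(np.count_nonzero(A) / (n * (n - 1)))


def is_connected(A) -> bool:
    ncomp, _ = connected_components(coo_matrix(A), directed=False)
    return int(ncomp) == 1


def k_grid(n: int, num: int = 50) -> np.ndarray:
    """Deduplicated integer grid of ``num`` k values, log-spaced on [1, N-1]."""
    ks = np.unique(np.rint(np.geomspace(1, n - 1, num)).astype(int))
    return ks


def gamma_grid(num: int = 50, lo: float = 1e-3, hi: float = 10.0) -> np.ndarray:
    """Log-spaced grid of RMST density parameters."""
    return np.geomspace(lo, hi, num)


def write_graph(A: np.ndarray, path: str | Path, fmt: str | None = None) -> None:
    """Write an adjacency matrix as Matrix Market coordinate or edge-list TSV.

    Edge lists carry one line per undirected edge, ``u <tab> v [<tab> w]``
    with ``u < v`` and 0-based indices; the weight column is included only
    for non-binary graphs.
    """
    path = Path(path)
    A = np.asarray(A, dtype=float)
    fmt = fmt or ("matrix-market" if path.suffix == ".mtx" else "edgelist")
    if fmt == "matrix-market":
        mmwrite(str(path), coo_matrix(A), symmetry="symmetric")
        return
    iu, ju = np.nonzero(np.triu(A, k=1))
    weights = A[iu, ju]
    binary = np.all(weights == 1.0)
    with open(path, "w") as fh:
        for u, v, w in zip(iu, ju, weights):
            if binary:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:.17g}\n")


def read_graph(path: str | Path, n_nodes: int | None = None) -> np.ndarray:
    """Read an adjacency matrix written by :func:`write_graph`."""
    path = Path(path)
    if path.suffix == ".mtx":
        A = np.asarray(mmread(str(path)).todense(), dtype=float)
        return A
    rows = np.loadtxt(path, ndmin=2)
    if rows.size == 0:
        raise ValueError(f"{path}: empty edge list")
    u = rows[:, 0].astype(int)
    v = rows[:, 1].astype(int)
    w = rows[:, 2] if rows.shape[1] > 2 else np.ones(len(u))
    n = n_nodes if n_nodes is not None else int(max(u.max(), v.max())) + 1
    A = np.zeros((n, n))
    A[u, v] = w
    A[v, u] = w
    return A
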