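"""Graph-quality diagnostics: subspace alignment and ratio of class separation.

Two complementary measures explain *why* a graph of the right density helps
a GCN:

* **Subspace alignment** ``S = cos(theta_1)`` — the cosine of the minimal
  principal angle between the leading principal-component subspaces of the
  graph-convolved features ``X_A = A_hat · X`` and of the one-hot ground
  truth ``Y``.  The number of components retained on each side is the
  smallest that explains at least a fraction ``p`` of the variance; the
  operating point ``p*`` is the grid value whose alignment profile best
  correlates (Pearson) with validation accuracy across a density sweep.
  Over-dense graphs average features towards a constant vector and drive
  ``S`` to 0 (subspaces orthogonal).

* **Ratio of class separation (RCS)** — from the classifier's output
  activations ``Z``, embed to 2-D (t-SNE), and take mean inter-class over
  mean intra-class pairwise Euclidean distance.  RCS = 1 is the mean-field
  limit (no separation); larger is better.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.manifold import TSNE

P_GRID = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


def class_masks(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inter- and intra-class pair indicator matrices.

    ``M_inter = 11^T - Y Y^T`` marks pairs in different classes,
    ``M_intra = Y Y^T - I`` marks distinct pairs in the same class;
    together with the identity they partition the all-ones matrix.
    """
    Y = np.asarray(Y, dtype=float)
    G = Y @ Y.T
    n = Y.shape[0]
    M_inter = np.ones((n, n)) - G
    M_intra = G - np.eye(n)
    return M_inter, M_intra


def pca_basis(M: np.ndarray, p: float) -> np.ndarray:
    """Orthonormal basis of the top principal components of ``M``.

    Columns are centered; the basis keeps the smallest number of leading
    left singular vectors whose cumulative explained-variance ratio
    reaches ``p``.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    M = np.asarray(M, dtype=float)
    Mc = M - M.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Mc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has zero variance (rank 0 after centering)")
    cum = np.cumsum(var) / total
    m = int(np.searchsorted(cum, p - 1e-12) + 1)
    m = min(m, np.count_nonzero(s > s[0] * 1e-12))
    return U[:, :m]


def subspace_alignment(
    X: np.ndarray, A_hat, Y: np.ndarray, p_star: float
) -> tuple[float, float]:
    """Alignment ``S = cos(theta_1)`` between PCA(A_hat X, p*) and PCA(Y, p*).

    Returns ``(S, theta_1)`` with ``S`` clipped to [0, 1] and ``theta_1``
    in radians.  Computed from the singular values of the cross-Gram of
    the two orthonormal bases (the largest singular value is ``cos`` of
    the minimal principal angle).
    """
    X_A = np.asarray(A_hat @ X)
    Q1 = pca_basis(X_A, p_star)
    Q2 = pca_basis(np.asarray(Y, dtype=float), p_star)
    svals = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
    S = float(np.clip(svals.max(initial=0.0), 0.0, 1.0))
    return S, float(np.arccos(S))


def select_p_star(
    alignments_per_p: dict[float, np.ndarray],
    val_accuracies: np.ndarray,
) -> tuple[float, float]:
    """Pick the explained-variance level whose alignment profile tracks accuracy.

    ``alignments_per_p`` maps each candidate ``p`` to the vector of
    alignment values across the density sweep; the chosen ``p*`` maximizes
    the Pearson correlation with the sweep's validation accuracies
    (ties go to the smaller ``p``).  Returns ``(p_star, correlation)``.
    """
    acc = np.asarray(val_accuracies, dtype=float)
    if len(alignments_per_p) == 0:
        raise ValueError("no candidate p values supplied")
    if acc.size < 3:
        raise ValueError("need at least 3 sweep points")
    if np.std(acc) == 0:
        raise ValueError("validation accuracies are constant; correlation undefined")
    best_p, best_r = None, -np.inf
    for p in sorted(alignments_per_p):
        s = np.asarray(alignments_per_p[p], dtype=float)
        if s.shape != acc.shape:
            raise ValueError("alignment and accuracy vectors differ in length")
        if np.std(s) == 0:
            continue
        r = float(pearsonr(s, acc)[0])
        if r > best_r + 1e-12:
            best_p, best_r = p, r
    if best_p is None:
        raise ValueError("all alignment profiles are constant")
    return float(best_p), float(best_r)


def embed_activations(
    Z: np.ndarray, seed: int = 0, perplexity: float = 30.0, n_iter: int = 1000
) -> np.ndarray:
    """2-D t-SNE embedding of the output activations (seeded)."""
    Z = np.asarray(Z, dtype=float)
    perplexity = min(perplexity, (Z.shape[0] - 1) / 3.0)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        random_state=seed,
        init="random",  # PCA init degenerates when Z has identical rows
    )
    return tsne.fit_transform(Z)


def ratio_class_separation(
    Z: np.ndarray,
    Y: np.ndarray,
    embed_seed: int = 0,
    embedding: np.ndarray | None = None,
) -> float:
    """RCS: mean inter-class over mean intra-class embedded distance.

    ``Z`` is embedded to 2-D with t-SNE unless a precomputed 2-D
    ``embedding`` is supplied (which makes the arithmetic deterministic
    and testable).  Classes of size one contribute no intra-class pairs
    and are effectively excluded (a warning is emitted).
    """
    Y = np.asarray(Y, dtype=float)
    sizes = Y.sum(axis=0)
    if np.any(sizes == 1):
        warnings.warn(
            f"{int((sizes == 1).sum())} singleton class(es) have no "
            "intra-class pairs and are excluded from the intra mean",
            stacklevel=2,
        )
    if np.all(sizes <= 1):
        raise ValueError("no class has an intra-class pair")
    Zp = np.asarray(embedding, dtype=float) if embedding is not None else \
        embed_activations(Z, seed=embed_seed)
    if Zp.shape[1] != 2:
        raise ValueError("embedding must be two-dimensional")
    D = squareform(pdist(Zp))
    M_inter, M_intra = class_masks(Y)
    inter = (D * M_inter).sum() / M_inter.sum()
    intra = (D * M_intra).sum() / M_intra.sum()
    if intra == 0:
        raise ZeroDivisionError("intra-class distances are all zero")
    return float(inter / intra)
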