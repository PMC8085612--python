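"""Two-layer graph convolutional network for semi-supervised classification.

The model is ``Z = softmax(A_hat · ReLU(A_hat · X · W0) · W1)`` with the
renormalized adjacency ``A_hat = D̃^{-1/2} (A + I) D̃^{-1/2}``,
``D̃_ii = 1 + Σ_j A_ij``.  With no graph (``A = 0``) the operator is the
identity and the model reduces exactly to a two-layer perceptron, which is
the reference baseline.

Training minimizes the cross-entropy over the labeled (training) rows plus
an L2 penalty on the first-layer weights, with inverted dropout on the
input of each layer, Glorot-uniform initialization, and early stopping
when the validation loss exceeds the mean of the trailing window.  The
forward and backward passes are written directly in numpy; adjacencies are
promoted to CSR sparse form when the graph is sparse enough to profit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse

_EPS = 1e-12


@dataclass
class TrainingConfig:
    """Hyperparameters of the GCN classifier.

    Defaults follow the standard two-layer setup: 2000 epochs, learning
    rate 0.01, early-stopping window 200, dropout 0.5, L2 penalty 5e-4 on
    the first layer, 16 hidden units.
    """

    epochs: int = 2000
    learning_rate: float = 0.01
    early_stop_window: int = 200
    dropout: float = 0.5
    l2: float = 5e-4
    hidden: int = 16
    seed: int = 0
    optimizer: str = "adam"          # "adam" or "sgd"
    monitor: str = "loss"            # early stopping on val "loss" or "accuracy"
    l2_all_layers: bool = False      # penalize W1 as well as W0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.epochs, self.early_stop_window, self.hidden) <= 0:
            raise ValueError("epochs, window and hidden width must be positive")
        if self.learning_rate <= 0 or self.l2 < 0:
            raise ValueError("invalid learning rate or L2 strength")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.monitor not in ("loss", "accuracy"):
            raise ValueError(f"unknown monitor {self.monitor!r}")


@dataclass
class GCNWeights:
    W0: np.ndarray
    W1: np.ndarray

    @property
    def hidden(self) -> int:
        return self.W0.shape[1]


@dataclass
class TrainingTrace:
    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


def normalize_adjacency(A, n: int | None = None):
    """Renormalized graph-convolution operator ``D̃^{-1/2}(A+I)D̃^{-1/2}``.

    Accepts a dense array or scipy sparse matrix (returned in kind); ``A``
    may be ``None`` or all-zero, in which case the operator is exactly the
    identity (the no-graph / MLP limit).
    """
    if A is None:
        if n is None:
            raise ValueError("n is required when A is None")
        return np.eye(n)
    if sparse.issparse(A):
        A = A.tocsr().astype(float)
        if (A != A.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must be hollow (zero diagonal)")
        if A.nnz and A.data.min() < 0:
            raise ValueError("adjacency weights must be nonnegative")
        n = A.shape[0]
        d = 1.0 + np.asarray(A.sum(axis=1)).ravel()
        inv_sqrt = 1.0 / np.sqrt(d)
        Dhalf = sparse.diags(inv_sqrt)
        return (Dhalf @ (A + sparse.eye(n)) @ Dhalf).tocsr()
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must be hollow (zero diagonal)")
    if np.any(A < 0):
        raise ValueError("adjacency weights must be nonnegative")
    d = 1.0 + A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return inv_sqrt[:, None] * (A + np.eye(A.shape[0])) * inv_sqrt[None, :]


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def gcn_forward(X, A_hat, weights: GCNWeights) -> np.ndarray:
    """Deterministic forward pass (dropout off): row-stochastic ``Z``."""
    H = A_hat @ (X @ weights.W0)
    H = np.maximum(H, 0.0)
    logits = A_hat @ (H @ weights.W1)
    return _softmax_rows(np.asarray(logits))


def cross_entropy_loss(
    Z: np.ndarray, Y: np.ndarray, labeled_idx: np.ndarray
) -> float:
    """Summed cross-entropy ``-Σ_{l∈labeled} Σ_c Y_lc ln Z_lc``.

    Probabilities are floored at 1e-12 so a confidently wrong prediction
    yields a large but finite loss.
    """
    labeled_idx = np.asarray(labeled_idx, dtype=int)
    if labeled_idx.size == 0:
        raise ValueError("labeled_idx must be non-empty")
    probs = np.clip(Z[labeled_idx], _EPS, None)
    return float(-(Y[labeled_idx] * np.log(probs)).sum())


def predict_accuracy(Z: np.ndarray, Y: np.ndarray, idx: np.ndarray) -> float:
    """Fraction of ``idx`` where argmax(Z) matches argmax(Y)."""
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValueError("idx must be non-empty")
    pred = np.argmax(Z[idx], axis=1)
    truth = np.argmax(Y[idx], axis=1)
    return float(np.mean(pred == truth))


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _as_operator(A_hat, dense_threshold: float = 0.25):
    """Choose dense vs CSR representation for repeated multiplication."""
    if sparse.issparse(A_hat):
        density = A_hat.nnz / (A_hat.shape[0] * A_hat.shape[1])
        return A_hat.toarray() if density > dense_threshold else A_hat.tocsr()
    A_hat = np.asarray(A_hat, dtype=float)
    density = np.count_nonzero(A_hat) / A_hat.size
    return A_hat if density > dense_threshold else sparse.csr_matrix(A_hat)


def train_gcn(
    X: np.ndarray,
    A,
    Y: np.ndarray,
    split,
    cfg: Optional[TrainingConfig] = None,
) -> tuple[GCNWeights, np.ndarray, TrainingTrace]:
    """Train the two-layer GCN and return (weights, activations, trace).

    Parameters
    ----------
    X
        N x F feature matrix (L1 row normalization is the caller's job).
    A
        Adjacency matrix (dense or sparse, symmetric, hollow), an already
        renormalized operator is *not* expected; pass ``None`` for the
        no-graph (MLP) limit.
    Y
        N x C one-hot membership matrix.
    split
        ``SplitSpec`` providing train/validation index sets.
    cfg
        ``TrainingConfig``; defaults used when omitted.

    The run is deterministic given ``cfg.seed``.  Raises ``FloatingPointError``
    if the loss diverges to NaN.
    """
    cfg = cfg or TrainingConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, n_feat = X.shape
    n_class = Y.shape[1]
    A_hat = _as_operator(normalize_adjacency(A, n=n))

    rng = np.random.default_rng(cfg.seed)
    W0 = glorot_uniform(rng, n_feat, cfg.hidden)
    W1 = glorot_uniform(rng, cfg.hidden, n_class)

    train_idx = np.asarray(split.train_idx, dtype=int)
    val_idx = np.asarray(split.val_idx, dtype=int)
    n_train = len(train_idx)
    train_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True

    keep = 1.0 - cfg.dropout

    # Adam state
    m0 = np.zeros_like(W0); v0 = np.zeros_like(W0)
    m1 = np.zeros_like(W1); v1 = np.zeros_like(W1)
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    trace = TrainingTrace()
    Z_eval = np.full((n, n_class), 1.0 / n_class)
    monitor_vals: list[float] = []

    for epoch in range(cfg.epochs):
        # ---- forward with dropout ----
        if cfg.dropout > 0:
            mask_x = (rng.random(X.shape) < keep) / keep
            X0 = X * mask_x
        else:
            X0 = X
        S1 = A_hat @ (X0 @ W0)
        S1 = np.asarray(S1)
        H = np.maximum(S1, 0.0)
        if cfg.dropout > 0:
            mask_h = (rng.random(H.shape) < keep) / keep
            H0 = H * mask_h
        else:
            H0 = H
        AH0 = np.asarray(A_hat @ H0)
        Z = _softmax_rows(AH0 @ W1)

        ce = cross_entropy_loss(Z, Y, train_idx) / n_train
        loss = ce + 0.5 * cfg.l2 * float((W0 ** 2).sum())
        if cfg.l2_all_layers:
            loss += 0.5 * cfg.l2 * float((W1 ** 2).sum())
        if not np.isfinite(loss):
            raise FloatingPointError(f"loss diverged at epoch {epoch}")

        # ---- backward ----
        dlogits = (Z - Y) * train_mask[:, None] / n_train
        dW1 = AH0.T @ dlogits
        if cfg.l2_all_layers:
            dW1 += cfg.l2 * W1
        dH0 = np.asarray(A_hat @ dlogits) @ W1.T     # A_hat is symmetric
        dH = dH0 * mask_h if cfg.dropout > 0 else dH0
        dS1 = dH * (S1 > 0)
        dW0 = X0.T @ np.asarray(A_hat @ dS1)
        dW0 += cfg.l2 * W0

        # ---- update ----
        if cfg.optimizer == "adam":
            t = epoch + 1
            m0 = beta1 * m0 + (1 - beta1) * dW0
            v0 = beta2 * v0 + (1 - beta2) * dW0 ** 2
            m1 = beta1 * m1 + (1 - beta1) * dW1
            v1 = beta2 * v1 + (1 - beta2) * dW1 ** 2
            corr1 = 1 - beta1 ** t
            corr2 = 1 - beta2 ** t
            W0 = W0 - cfg.learning_rate * (m0 / corr1) / (np.sqrt(v0 / corr2) + eps)
            W1 = W1 - cfg.learning_rate * (m1 / corr1) / (np.sqrt(v1 / corr2) + eps)
        else:
            W0 = W0 - cfg.learning_rate * dW0
            W1 = W1 - cfg.learning_rate * dW1

        # ---- evaluation pass (dropout off) ----
        Z_eval = gcn_forward(X, A_hat, GCNWeights(W0, W1))
        val_ce = cross_entropy_loss(Z_eval, Y, val_idx) / len(val_idx)
        trace.loss.append(loss)
        trace.val_loss.append(val_ce)
        trace.train_accuracy.append(predict_accuracy(Z_eval, Y, train_idx))
        trace.val_accuracy.append(predict_accuracy(Z_eval, Y, val_idx))
        trace.stopped_epoch = epoch + 1

        # early stopping: current monitor worse than the trailing-window mean
        monitor_vals.append(
            val_ce if cfg.monitor == "loss" else -trace.val_accuracy[-1]
        )
        w = cfg.early_stop_window
        if epoch + 1 > w and monitor_vals[-1] > np.mean(monitor_vals[-1 - w:-1]):
            break

    return GCNWeights(W0, W1), Z_eval, trace
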