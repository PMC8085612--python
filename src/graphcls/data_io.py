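"""Feature-table and label I/O, splits, and the stochastic-block-model generator.

Every downstream module works on plain numpy arrays: an ``N x F`` feature
matrix ``X``, a length-``N`` integer label vector, and an ``N x C`` one-hot
membership matrix ``Y``.  This module provides the loaders that produce
them, the L1 row normalization applied before any distance computation, the
train/validation/test splitter (5% / 10% / 85% by default, with training
samples evenly distributed across classes), and a synthetic generator with
a stochastic-block-model ground truth so that the whole pipeline is
testable without downloading anything.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.05, 0.10, 0.85)


@dataclass
class FeatureMatrix:
    """An N x F numeric feature table with per-sample identifiers."""

    X: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be two-dimensional")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(self.X.shape[0])]
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("sample_ids length does not match row count")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def F(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/test index sets partitioning ``range(N)``."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.val_idx) + len(self.test_idx)


@dataclass
class SBMConfig:
    """Parameters of the stochastic-block-model synthetic dataset.

    The generator draws a symmetric 0/1 block matrix ``B`` with
    ``P(B_ij = 1) = p_in`` for samples in the same block and ``p_out``
    otherwise, sets the diagonal to 1, then flips each entry independently
    with probability ``noise_flip``.  Each sample's feature vector is its
    row of the noisy matrix, so ``F = N``; the block identity is the label.
    """

    N: int = 120
    C: int = 4
    block_sizes: tuple[int, ...] | None = None
    p_in: float = 0.8
    p_out: float = 0.1
    noise_flip: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_sizes is None:
            base, rem = divmod(self.N, self.C)
            self.block_sizes = tuple(
                base + (1 if c < rem else 0) for c in range(self.C)
            )
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if sum(self.block_sizes) != self.N:
            raise ValueError(
                f"block_sizes {self.block_sizes} do not sum to N={self.N}"
            )
        if len(self.block_sizes) != self.C:
            raise ValueError("block_sizes length must equal C")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.noise_flip <= 1.0:
            raise ValueError("noise_flip must be a probability")

    @classmethod
    def from_json(cls, path: str | Path) -> "SBMConfig":
        with open(path) as fh:
            payload = json.load(fh)
        if "block_sizes" in payload and payload["block_sizes"] is not None:
            payload["block_sizes"] = tuple(payload["block_sizes"])
        return cls(**payload)


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        return "tsv"
    if suffix == ".mtx":
        return "matrix-market"
    return "csv"


def load_feature_table(
    path: str | Path, fmt: str | None = None, header: bool = False
) -> FeatureMatrix:
    """Load a dense numeric sample-by-feature table.

    Parameters
    ----------
    path
        CSV, TSV, or Matrix Market file.
    fmt
        One of ``{"csv", "tsv", "matrix-market"}``; inferred from the file
        suffix when omitted.
    header
        Whether delimited files carry a header row (ignored for Matrix
        Market).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    if fmt == "matrix-market":
        M = mmread(str(path))
        if hasattr(M, "todense"):
            M = M.todense()
        return FeatureMatrix(np.asarray(M, dtype=float))
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        frame = pd.read_csv(
            path, sep=sep, header=0 if header else None, dtype=float
        )
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unparsable file") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    except ValueError as exc:
        raise TypeError(f"{path}: non-numeric cell ({exc})") from exc
    if frame.isna().any().any():
        bad = int(frame.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing value in data row {bad}")
    return FeatureMatrix(frame.to_numpy(dtype=float))


def write_feature_table(
    X: np.ndarray | FeatureMatrix, path: str | Path, fmt: str | None = None
) -> None:
    """Write a feature matrix as CSV, TSV, or Matrix Market (dense array)."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "matrix-market":
        mmwrite(str(path), X)
        return
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    np.savetxt(path, X, delimiter=sep, fmt="%.17g")


def load_labels(path: str | Path) -> np.ndarray:
    """Load a single-column CSV of integer class labels."""
    labels = np.loadtxt(path, dtype=int, ndmin=1)
    if labels.ndim != 1:
        raise ValueError("label file must contain a single column")
    if labels.min() < 0:
        raise ValueError("labels must be nonnegative integers")
    return labels


def one_hot(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """0/1 membership matrix ``Y`` (N x C) from an integer label vector."""
    labels = np.asarray(labels, dtype=int)
    C = int(labels.max()) + 1 if n_classes is None else int(n_classes)
    Y = np.zeros((len(labels), C))
    Y[np.arange(len(labels)), labels] = 1.0
    return Y


def l1_row_normalize(X: np.ndarray | FeatureMatrix) -> np.ndarray:
    """Scale every row to unit L1 norm.

    Raises
    ------
    ValueError
        If any row is entirely zero (listing the offending row indices).
    """
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    norms = np.abs(X).sum(axis=1)
    zero_rows = np.flatnonzero(norms == 0)
    if zero_rows.size:
        raise ValueError(
            f"cannot L1-normalize all-zero rows at indices {zero_rows.tolist()}"
        )
    return X / norms[:, None]


def make_splits(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitSpec:
    """Draw a train/validation/test partition of ``range(N)``.

    The training set holds ``round(f_train * N)`` samples spread evenly
    across classes (per-class counts differ by at most one); validation and
    test sets are drawn uniformly at random from the pooled remainder.
    Deterministic given ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    N = len(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} must sum to 1")
    C = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=C)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"classes with zero samples: {empty.tolist()}")

    rng = np.random.default_rng(seed)
    n_train = int(round(fractions[0] * N))
    # bump upward so no class is left without a training sample
    n_train = max(n_train, C)
    base, rem = divmod(n_train, C)
    extra = np.zeros(C, dtype=int)
    if rem:
        extra[rng.choice(C, size=rem, replace=False)] = 1
    per_class = base + extra
    if np.any(per_class > counts):
        raise ValueError(
            "a class has too few samples for the requested training fraction"
        )

    train_parts = []
    for c in range(C):
        members = np.flatnonzero(labels == c)
        members = rng.permutation(members)
        train_parts.append(members[: per_class[c]])
    train_idx = np.sort(np.concatenate(train_parts))

    remainder = np.setdiff1d(np.arange(N), train_idx)
    remainder = rng.permutation(remainder)
    n_val = int(round(fractions[1] * N))
    val_idx = np.sort(remainder[:n_val])
    test_idx = np.sort(remainder[n_val:])
    return SplitSpec(train_idx, val_idx, test_idx, tuple(fractions), seed)


def generate_sbm_dataset(cfg: SBMConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw a stochastic-block-model feature matrix and its labels.

    Returns
    -------
    X : ndarray of shape (N, N)
        Rows of the noisy symmetric block matrix (0/1 floats).
    labels : ndarray of shape (N,)
        Block identity of every sample.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = np.repeat(np.arange(cfg.C), cfg.block_sizes)
    same_block = labels[:, None] == labels[None, :]
    P = np.where(same_block, cfg.p_in, cfg.p_out)

    draws = rng.random((cfg.N, cfg.N))
    B = np.triu((draws < P).astype(float), k=1)
    B = B + B.T
    np.fill_diagonal(B, 1.0)  # self-similarity, avoids all-zero rows

    if cfg.noise_flip > 0:
        flip = np.triu(rng.random((cfg.N, cfg.N)) < cfg.noise_flip)
        flip = flip | flip.T
        B = np.where(flip, 1.0 - B, B)

    dup = _count_duplicate_rows(B)
    if dup:
        logger.warning(
            "SBM features contain %d duplicate rows (zero distances downstream)",
            dup,
        )
    return B, labels


def _count_duplicate_rows(X: np.ndarray) -> int:
    _, counts = np.unique(X, axis=0, return_counts=True)
    return int((counts - 1).sum())


def warn_on_duplicate_rows(X: np.ndarray) -> int:
    """Log a warning if the feature table contains duplicate rows."""
    dup = _count_duplicate_rows(np.asarray(X))
    if dup:
        warnings.warn(
            f"{dup} duplicate feature rows create zero pairwise distances",
            stacklevel=2,
        )
    return dup
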