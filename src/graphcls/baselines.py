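"""Graph-less reference classifiers with single-knob validation tuning.

Four baselines mirror the comparison table: an MLP (identically the GCN
with no graph), a k-nearest-neighbor vote, an RBF-kernel SVM, and a
random forest.  Each method tunes exactly one hyperparameter on the
validation split — number of neighbors, regularization strength, or
maximum tree depth — with every other setting left at the library
default; the chosen value maximizes validation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from graphcls.gcn import TrainingConfig, predict_accuracy, train_gcn

DEFAULT_GRIDS: dict[str, tuple] = {
    "knnc": tuple(range(1, 30, 2)),
    "svm_rbf": (0.01, 0.1, 1.0, 10.0, 100.0),
    "random_forest": (2, 4, 8, 16, 32, None),
}

TUNED_PARAM = {
    "mlp": None,
    "knnc": "n_neighbors",
    "svm_rbf": "regularization",
    "random_forest": "max_depth",
}


@dataclass
class BaselineSpec:
    """A baseline method, its single tuned hyperparameter, and the grid."""

    method: str
    grid: Sequence | None = None
    seed: int = 0
    gcn_config: TrainingConfig | None = None

    def __post_init__(self) -> None:
        if self.method not in TUNED_PARAM:
            raise ValueError(f"unknown baseline {self.method!r}")
        if self.grid is None:
            self.grid = DEFAULT_GRIDS.get(self.method, ())
        self.grid = tuple(self.grid)
        if self.method != "mlp" and len(self.grid) == 0:
            raise ValueError("hyperparameter grid is empty")

    @property
    def tuned_param_name(self) -> str | None:
        return TUNED_PARAM[self.method]


def _make_estimator(method: str, value, seed: int):
    if method == "knnc":
        return KNeighborsClassifier(n_neighbors=int(value))
    if method == "svm_rbf":
        return SVC(kernel="rbf", C=float(value), random_state=seed)
    if method == "random_forest":
        depth = None if value is None else int(value)
        return RandomForestClassifier(max_depth=depth, random_state=seed)
    raise ValueError(method)


def fit_reference_classifier(
    X: np.ndarray,
    Y: np.ndarray,
    split,
    spec: BaselineSpec,
) -> tuple[float, object, dict]:
    """Tune on the validation split, evaluate on the test split.

    Returns ``(test_accuracy, chosen_hyperparameter, info)``.  The MLP
    variant routes through :func:`graphcls.gcn.train_gcn` with no graph,
    so its behavior is bit-for-bit the GCN's no-graph limit; the others
    are fitted on the training rows only.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    labels = np.argmax(Y, axis=1)

    if spec.method == "mlp":
        cfg = spec.gcn_config or TrainingConfig(seed=spec.seed)
        _, Z, trace = train_gcn(X, None, Y, split, cfg)
        test_acc = predict_accuracy(Z, Y, split.test_idx)
        info = {
            "val_accuracy": predict_accuracy(Z, Y, split.val_idx),
            "stopped_epoch": trace.stopped_epoch,
        }
        return test_acc, None, info

    train, val, test = split.train_idx, split.val_idx, split.test_idx
    grid = spec.grid
    if spec.method == "knnc":
        # a neighbor vote cannot use more neighbors than training samples
        grid = tuple(v for v in grid if int(v) <= len(train)) or (1,)
    best_val, best_value, best_est = -np.inf, None, None
    val_curve = []
    for value in grid:
        est = _make_estimator(spec.method, value, spec.seed)
        est.fit(X[train], labels[train])
        acc = float(np.mean(est.predict(X[val]) == labels[val]))
        val_curve.append((value, acc))
        if acc > best_val:
            best_val, best_value, best_est = acc, value, est
    test_acc = float(np.mean(best_est.predict(X[test]) == labels[test]))
    info = {"val_accuracy": best_val, "val_curve": val_curve}
    return test_acc, best_value, info
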