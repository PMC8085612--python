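"""Orchestration: density sweep, graph selection, diagnostics, sparsification.

The full protocol, for one dataset and one construction method:

1. sweep the density parameter (``k`` or ``gamma``) over a grid (50 values
   by default), training the GCN from 10 random initializations at every
   grid point and recording mean validation accuracy, edge density, and
   the alignment diagnostic at every candidate explained-variance level;
2. select the grid point maximizing mean validation accuracy (ties to the
   lower edge density) — the test split plays no role in selection;
3. report mean ± sd test accuracy at the optimum, pick ``p*`` by
   correlating alignment with validation accuracy, and optionally
   correlate the ratio of class separation the same way;
4. feed the optimized graph to the spectral sparsification sweep.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from graphcls.baselines import BaselineSpec, fit_reference_classifier
from graphcls.data_io import (
    SBMConfig,
    generate_sbm_dataset,
    l1_row_normalize,
    make_splits,
    one_hot,
)
from graphcls.diagnostics import (
    P_GRID,
    ratio_class_separation,
    select_p_star,
    subspace_alignment,
)
from graphcls.gcn import (
    TrainingConfig,
    normalize_adjacency,
    predict_accuracy,
    train_gcn,
)
from graphcls.graph_construction import (
    build_cknn,
    build_knn,
    build_mknn,
    build_rmst,
    edge_density,
    gamma_grid,
    k_grid,
    minimum_spanning_tree,
    pairwise_euclidean,
)
from graphcls.sparsification import sparsification_sweep

logger = logging.getLogger(__name__)

_BUILDERS = {
    "knn": lambda D, p, mst: build_knn(D, int(p), mst=mst),
    "mknn": lambda D, p, mst: build_mknn(D, int(p), mst=mst),
    "cknn": lambda D, p, mst: build_cknn(D, int(p), delta=1.0, mst=mst),
    "rmst": lambda D, p, mst: build_rmst(D, float(p), k=1, mst=mst),
}


def default_grid(method: str, n: int, num: int = 50) -> np.ndarray:
    """Density-parameter grid: log-spaced k for neighbor methods, gamma for RMST."""
    if method == "rmst":
        return gamma_grid(num)
    return k_grid(n, num)


def run_seeds(seed: int, n_runs: int) -> list[int]:
    """Per-run RNG seeds derived from one base seed."""
    return [int(s) for s in
            (np.random.SeedSequence(seed).generate_state(n_runs) % (2**31))]


@dataclass
class DensitySweepResult:
    """Records of one density sweep plus what selection needs to rebuild."""

    method: str
    records: list[dict]
    alignments_per_p: dict[float, np.ndarray]
    D: np.ndarray = field(repr=False)
    mst: object = field(repr=False)
    n_runs: int = 10

    @property
    def params(self) -> np.ndarray:
        return np.array([r["param"] for r in self.records if not r["failed"]])

    @property
    def val_accuracy_mean(self) -> np.ndarray:
        return np.array(
            [r["val_accuracy_mean"] for r in self.records if not r["failed"]]
        )

    def best_index(self) -> int:
        ok = [r for r in self.records if not r["failed"]]
        if not ok:
            raise ValueError("every sweep point failed")
        best = max(ok, key=lambda r: (r["val_accuracy_mean"], -r["edge_density"]))
        return self.records.index(best)


def density_sweep(
    X: np.ndarray,
    Y: np.ndarray,
    split,
    method: str,
    grid: np.ndarray | None = None,
    n_runs: int = 10,
    seed: int = 0,
    cfg: TrainingConfig | None = None,
    p_grid: tuple = P_GRID,
    compute_alignment: bool = True,
    compute_rcs: bool = False,
    rcs_runs: int = 1,
    D: np.ndarray | None = None,
) -> DensitySweepResult:
    """Train graph + GCN across a density grid; see the module docstring.

    ``X`` must already be L1 row normalized.  Deterministic given ``seed``:
    the same per-run seed list is reused at every grid point, so runs vary
    only in weight initialization and dropout, not in the graph.
    """
    if method not in _BUILDERS:
        raise ValueError(f"unknown construction {method!r}")
    cfg = cfg or TrainingConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    D = pairwise_euclidean(X) if D is None else D
    mst = minimum_spanning_tree(D)
    grid = default_grid(method, X.shape[0]) if grid is None else np.asarray(grid)
    if len(grid) > 50:
        raise ValueError("grid is limited to 50 density values")
    seeds = run_seeds(seed, n_runs)

    records: list[dict] = []
    align_acc: dict[float, list[float]] = {p: [] for p in p_grid}
    for param in grid:
        rec: dict = {"param": float(param), "failed": False}
        try:
            A = _BUILDERS[method](D, param, mst)
        except Exception as exc:  # noqa: BLE001 — recorded, not fatal
            logger.warning("grid point %s failed: %s", param, exc)
            rec.update({"failed": True, "error": str(exc)})
            records.append(rec)
            continue
        rec["edge_density"] = edge_density(A)
        val_accs, test_accs, rcs_vals = [], [], []
        for r, s in enumerate(seeds):
            run_cfg = TrainingConfig(**{**cfg.__dict__, "seed": s})
            _, Z, _ = train_gcn(X, A, Y, split, run_cfg)
            val_accs.append(predict_accuracy(Z, Y, split.val_idx))
            test_accs.append(predict_accuracy(Z, Y, split.test_idx))
            if compute_rcs and r < rcs_runs:
                rcs_vals.append(
                    ratio_class_separation(Z, Y, embed_seed=seed)
                )
        rec["val_accuracy_mean"] = float(np.mean(val_accs))
        rec["val_accuracy_sd"] = float(np.std(val_accs))
        rec["test_accuracy_mean"] = float(np.mean(test_accs))
        rec["test_accuracy_sd"] = float(np.std(test_accs))
        if compute_rcs:
            rec["rcs_mean"] = float(np.mean(rcs_vals))
        if compute_alignment:
            A_hat = normalize_adjacency(A)
            for p in p_grid:
                S, _ = subspace_alignment(X, A_hat, Y, p)
                align_acc[p].append(S)
            rec["alignment"] = {float(p): align_acc[p][-1] for p in p_grid}
        records.append(rec)

    alignments = {p: np.array(v) for p, v in align_acc.items() if v}
    return DensitySweepResult(
        method=method, records=records, alignments_per_p=alignments,
        D=D, mst=mst, n_runs=n_runs,
    )


def select_optimal_graph(result: DensitySweepResult) -> tuple[np.ndarray, dict]:
    """Rebuild the graph at the argmax of mean validation accuracy.

    Ties are broken toward the lower edge density.  Returns the adjacency
    and the winning sweep record.
    """
    idx = result.best_index()
    rec = result.records[idx]
    A = _BUILDERS[result.method](result.D, rec["param"], result.mst)
    return A, rec


def _dataset_from_config(config: dict):
    if "sbm" in config:
        cfg = SBMConfig(**config["sbm"])
        X_raw, labels = generate_sbm_dataset(cfg)
    else:
        from graphcls.data_io import load_feature_table, load_labels

        X_raw = load_feature_table(config["features"]).X
        labels = load_labels(config["labels"])
    X = l1_row_normalize(X_raw)
    Y = one_hot(labels)
    return X, Y, labels


def run_full_experiment(config: dict) -> dict:
    """Execute the complete protocol described in the module docstring.

    ``config`` keys (all optional unless noted):

    - ``sbm``: SBMConfig fields, or ``features``/``labels`` paths (required,
      one of the two)
    - ``constructions``: list among {knn, mknn, cknn, rmst} (default all)
    - ``grid_size``: density values per sweep (default 50)
    - ``n_runs``: GCN restarts per grid point (default 10)
    - ``seed``: base seed (default 0)
    - ``split_fractions``: train/val/test fractions (default 0.05/0.10/0.85)
    - ``gcn``: TrainingConfig overrides
    - ``baselines``: list among {mlp, knnc, svm_rbf, random_forest}
    - ``sparsify``: bool, run the sparsification sweep on the best CkNN
      graph (default True when cknn is swept)
    - ``compute_rcs``: bool (default True)
    - ``out_dir``: directory for report.json / sweep CSVs / graph files
    """
    seed = int(config.get("seed", 0))
    X, Y, labels = _dataset_from_config(config)
    n = X.shape[0]
    fractions = tuple(config.get("split_fractions", (0.05, 0.10, 0.85)))
    split = make_splits(labels, fractions=fractions, seed=seed)
    gcn_cfg = TrainingConfig(**config.get("gcn", {}))
    n_runs = int(config.get("n_runs", 10))
    grid_size = int(config.get("grid_size", 50))
    constructions = list(config.get("constructions", ["knn", "mknn", "cknn", "rmst"]))
    compute_rcs = bool(config.get("compute_rcs", True))

    report: dict = {"seed": seed, "n_samples": n, "split": {
        "fractions": fractions,
        "n_train": len(split.train_idx),
        "n_val": len(split.val_idx),
        "n_test": len(split.test_idx),
    }}

    # --- baselines ---
    baseline_methods = config.get(
        "baselines", ["mlp", "knnc", "svm_rbf", "random_forest"]
    )
    report["baselines"] = {}
    mlp_test = None
    for method in baseline_methods:
        spec = BaselineSpec(method=method, seed=seed,
                            gcn_config=gcn_cfg if method == "mlp" else None)
        if method == "mlp":
            # average over the same restarts as the GCN sweeps
            accs = []
            for s in run_seeds(seed, n_runs):
                run_cfg = TrainingConfig(**{**gcn_cfg.__dict__, "seed": s})
                _, Z, _ = train_gcn(X, None, Y, split, run_cfg)
                accs.append(predict_accuracy(Z, Y, split.test_idx))
            mlp_test = float(np.mean(accs))
            report["baselines"]["mlp"] = {
                "test_accuracy_mean": mlp_test,
                "test_accuracy_sd": float(np.std(accs)),
            }
        else:
            acc, chosen, info = fit_reference_classifier(X, Y, split, spec)
            report["baselines"][method] = {
                "test_accuracy": acc,
                "chosen_hyperparameter": chosen,
                "val_accuracy": info["val_accuracy"],
            }

    # --- density sweeps ---
    D = pairwise_euclidean(X)
    report["sweeps"] = {}
    improvements = []
    best_cknn_graph = None
    for method in constructions:
        grid = default_grid(method, n, grid_size)
        result = density_sweep(
            X, Y, split, method, grid=grid, n_runs=n_runs, seed=seed,
            cfg=gcn_cfg, compute_rcs=compute_rcs, D=D,
        )
        A_opt, rec = select_optimal_graph(result)
        entry = {
            "grid": [float(g) for g in grid],
            "records": result.records,
            "optimal_param": rec["param"],
            "optimal_edge_density": rec["edge_density"],
            "test_accuracy_mean": rec["test_accuracy_mean"],
            "test_accuracy_sd": rec["test_accuracy_sd"],
        }
        # diagnostics correlations across the sweep
        try:
            p_star, r_align = select_p_star(
                result.alignments_per_p, result.val_accuracy_mean
            )
            entry["p_star"] = p_star
            entry["alignment_accuracy_pearson"] = r_align
        except ValueError as exc:
            entry["alignment_accuracy_pearson_error"] = str(exc)
        if compute_rcs:
            rcs = np.array([r["rcs_mean"] for r in result.records
                            if not r["failed"]])
            acc = result.val_accuracy_mean
            if np.std(rcs) > 0 and np.std(acc) > 0:
                from scipy.stats import pearsonr
                entry["rcs_accuracy_pearson"] = float(pearsonr(rcs, acc)[0])
        if mlp_test is not None:
            improvements.append(rec["test_accuracy_mean"] - mlp_test)
        report["sweeps"][method] = entry
        if method == "cknn":
            best_cknn_graph = A_opt

    if improvements:
        report["average_improvement_over_mlp"] = float(np.mean(improvements))

    # --- sparsification of the optimized CkNN graph ---
    do_sparsify = config.get("sparsify", best_cknn_graph is not None)
    if do_sparsify and best_cknn_graph is not None:
        from graphcls.sparsification import sigma_grid

        sigmas = sigma_grid(n, int(config.get("sigma_grid_size", 50)))
        A_sparse, sp_report = sparsification_sweep(
            best_cknn_graph, X, Y, split, sigmas=sigmas, n_runs=n_runs,
            cfg=gcn_cfg, seed=seed, mst_edges=None,
            test_fallback=bool(config.get("test_fallback", True)),
        )
        report["sparsification"] = sp_report

    out_dir = config.get("out_dir")
    if out_dir:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    for method, entry in report.get("sweeps", {}).items():
        rows = [r for r in entry["records"] if not r.get("failed")]
        frame = pd.DataFrame(
            [{k: v for k, v in r.items() if not isinstance(v, dict)}
             for r in rows]
        )
        frame.to_csv(out_dir / f"sweep_{method}.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
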