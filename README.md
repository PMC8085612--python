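# graphcls

Semi-supervised sample classification from a feature table alone, by
constructing a geometric graph over the samples and using it in a graph
convolutional network (GCN).

Many datasets — transcriptomes, text embeddings, engineered image
features — come as a plain `N x F` matrix with labels for only a few
samples. `graphcls` derives a sparse graph from the features themselves
(no relational data required), so that a GCN can diffuse label
information between similar samples. The package is for practitioners who
want to test whether a feature-derived graph of the right density
improves over graph-less classifiers on their table, and for method
developers who need the individual pieces (graph constructions, a
reference GCN, diagnostics, spectral sparsification) as a library.

## The method

Feature vectors are L1 row normalized and compared by Euclidean distance
`d(i,j) = ||X_i − X_j||_2`. Four constructions, each anchored on the
minimum spanning tree (so every graph is connected) and controlled by one
density knob:

- **kNN** — edge if `d(i,j) ≤ d(i,i_k)` *or* `d(i,j) ≤ d(j,j_k)`;
- **MkNN** — mutual variant (*and*), bounding pre-union degrees by `k`;
- **CkNN** — `d(i,j) < δ·√(d(i,i_k)·d(j,j_k))` with `δ = 1`, a
  density-adaptive neighborhood scale;
- **RMST** — `d(i,j) < maxpath_MST(i,j) + γ·(d(i,i_1)+d(j,j_1))`, adding
  direct edges competitive with the MST-path bottleneck.

The two-layer GCN `Z = softmax(Â ReLU(Â X W₀) W₁)` with
`Â = D̃^{-1/2}(A+I)D̃^{-1/2}` is trained on 5% labeled samples (10% for
validation, the rest test). The density knob is swept from sparse to
dense, 10 restarts per value; the graph maximizing mean validation
accuracy wins. The no-graph limit *is* a two-layer MLP; the
complete-graph limit collapses to mean-field (random assignment). Two
diagnostics explain the sweet spot: the subspace alignment
`S = cos θ₁(Â X, Y)` between convolved features and ground truth, and
the ratio of class separation (RCS) of the output activations' 2-D
embedding. Finally, effective-resistance (spectral) sparsification
compresses the optimized graph while preserving the Laplacian quadratic
form within `1 ± σ`.

## Worked example

```python
import numpy as np
from graphcls import *

# a 4-block stochastic block model with 20% flip noise: classes are
# recoverable but not trivially, so graph density matters
cfg = SBMConfig(N=100, C=4, p_in=1.0, p_out=0.0, noise_flip=0.2, seed=7)
X_raw, labels = generate_sbm_dataset(cfg)
X = l1_row_normalize(X_raw)
Y = one_hot(labels)
split = make_splits(labels, seed=7)          # 5% train / 10% val / 85% test

result = density_sweep(X, Y, split, "cknn",
                       grid=np.array([1, 2, 5, 12, 30, 70]),
                       n_runs=10, seed=0)
A_opt, best = select_optimal_graph(result)
print(f"optimal k = {best['param']:.0f}, edge density = {best['edge_density']:.3f}")
print(f"GCN test accuracy  = {100 * best['test_accuracy_mean']:.1f}%")

_, Z, _ = train_gcn(X, None, Y, split, TrainingConfig(seed=0))
print(f"MLP test accuracy  = {100 * predict_accuracy(Z, Y, split.test_idx):.1f}%")

p_star, r = select_p_star(result.alignments_per_p, result.val_accuracy_mean)
print(f"p* = {p_star:.2f}, Pearson(alignment, val accuracy) = {r:.3f}")
```

Output:

```
optimal k = 5, edge density = 0.039
GCN test accuracy  = 100.0%
MLP test accuracy  = 95.3%
p* = 0.55, Pearson(alignment, val accuracy) = 0.987
```

The sweep finds an interior optimum (`k = 5`, 3.9% of possible edges):
sparser graphs approach the MLP's 95.3%, denser ones decay toward the
25% mean-field rate, and the optimized graph classifies the test split
perfectly. The alignment diagnostic tracks validation accuracy almost
exactly (Pearson 0.987 at its best explained-variance level), which is
the mechanism by which the right graph helps: convolution with it rotates
the feature subspace toward the label subspace.

A command-line interface mirrors the library:

```bash
graphcls build-graph --method cknn --param 5 --features X.csv --out graph.mtx
graphcls train --features X.csv --labels y.csv --graph graph.mtx --runs 10
graphcls run --config experiment.json     # full sweep + diagnostics + sparsification
```

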