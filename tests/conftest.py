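import numpy as np
import pytest

from graphcls import (
    SBMConfig,
    generate_sbm_dataset,
    l1_row_normalize,
    make_splits,
    one_hot,
    pairwise_euclidean,
)


@pytest.fixture(scope="session")
def line_D():
    """Distance matrix of 1-D points (0, 1, 3, 10) — the running fixture."""
    X = np.array([[0.0], [1.0], [3.0], [10.0]])
    return pairwise_euclidean(X)


@pytest.fixture(scope="session")
def separable_sbm():
    """Four 25-sample blocks, p_in=1, p_out=0, 5% flip noise.

    Classes remain perfectly separable but rows are distinct, so every
    construction (including CkNN) applies.
    """
    cfg = SBMConfig(N=100, C=4, p_in=1.0, p_out=0.0, noise_flip=0.05, seed=7)
    X_raw, labels = generate_sbm_dataset(cfg)
    X = l1_row_normalize(X_raw)
    Y = one_hot(labels)
    split = make_splits(labels, seed=7)
    return X, Y, labels, split


@pytest.fixture(scope="session")
def noisy_sbm():
    """Same block structure with 20% flip noise.

    Accuracy is no longer saturated across the density grid, so the
    selected optimum carries redundant within-block edges — the regime
    where graphs beat the MLP and sparsification has room to act.
    """
    cfg = SBMConfig(N=100, C=4, p_in=1.0, p_out=0.0, noise_flip=0.2, seed=7)
    X_raw, labels = generate_sbm_dataset(cfg)
    X = l1_row_normalize(X_raw)
    Y = one_hot(labels)
    split = make_splits(labels, seed=7)
    return X, Y, labels, split


@pytest.fixture(scope="session")
def noiseless_sbm():
    """Two 3-sample blocks with p_in=1, p_out=0 and no noise."""
    cfg = SBMConfig(N=6, C=2, block_sizes=(3, 3), p_in=1.0, p_out=0.0,
                    noise_flip=0.0, seed=0)
    return generate_sbm_dataset(cfg)
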