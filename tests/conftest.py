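import numpy as np
import pytest


@pytest.fixture
def toy8():
    """Fixed 8-point, 2-class, 2-D dataset for closed-form checks."""
    X = np.array([
        [0.0, 0.0], [1.0, 0.5], [0.5, 1.5], [1.5, 1.0],
        [4.0, 3.0], [5.0, 4.5], [4.5, 3.5], [5.5, 5.0],
    ])
    y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    return X, y


@pytest.fixture
def label_matrix_3x5():
    """The worked 3-unit, 5-annotator majority-vote example (row 3 deadlocks)."""
    return np.array([
        [1, 1, 1, 3, 1],
        [3, 2, 3, 1, 3],
        [1, 1, 2, 3, 3],
    ])


@pytest.fixture
def single_obs_posteriors():
    """Single-observation soft-scoring example: per-annotator posteriors,
    hard labels and the current estimated label."""
    z = np.array([
        [[0.8, 0.1, 0.1]],
        [[0.5, 0.3, 0.2]],
        [[0.4, 0.5, 0.1]],
    ])  # (M=3, N=1, G=3)
    labels = np.array([[1, 1, 2]])
    estimated = np.array([1])
    return z, labels, estimated


def make_gaussian_classes(seed, means, n_per_class, cov_chol=None):
    """Simple labeled Gaussian sampler used across tests."""
    rng = np.random.default_rng(seed)
    means = np.asarray(means, dtype=float)
    G, p = means.shape
    X, y = [], []
    for g in range(G):
        z = rng.standard_normal((n_per_class, p))
        if cov_chol is not None:
            z = z @ np.asarray(cov_chol[g]).T
        X.append(means[g] + z)
        y.append(np.full(n_per_class, g + 1))
    return np.vstack(X), np.concatenate(y)
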