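import numpy as np
import pytest

from grainpred import OmicsMatrix, SimConfig, compute_kernel
from grainpred.simulate import simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scale synthetic dataset shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=101))


@pytest.fixture(scope="session")
def small_kernel():
    """Standardized 40-line feature matrix and its relationship kernel."""
    rng = np.random.default_rng(7)
    n, m = 40, 120
    W = rng.standard_normal((n, m))
    W = (W - W.mean(axis=0)) / W.std(axis=0)
    mat = OmicsMatrix(W, np.array([f"L{i}" for i in range(n)]),
                      np.array([f"f{j}" for j in range(m)]), "marker", True)
    return mat, compute_kernel(mat)


def standardized_matrix(rng, n, m, kind="marker"):
    W = rng.standard_normal((n, m))
    W = (W - W.mean(axis=0)) / W.std(axis=0)
    return OmicsMatrix(W, np.array([f"L{i}" for i in range(n)]),
                       np.array([f"f{j}" for j in range(m)]), kind, True)
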