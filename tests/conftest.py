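import numpy as np
import pytest

from scsemi.data_io import CountMatrix, preprocess
from scsemi.splat_sim import SimParams, simulate


@pytest.fixture(scope="session")
def tiny_cm() -> CountMatrix:
    """3 cells x 2 genes, hand-checkable."""
    return CountMatrix(
        counts=np.array([[2, 0], [1, 3], [0, 4]]),
        cell_ids=["a", "b", "c"],
        gene_ids=["g1", "g2"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small separable simulation: 4 imbalanced groups, strong DE."""
    params = SimParams(n_cells=200, n_genes=120,
                       group_prob=(0.1, 0.2, 0.3, 0.4),
                       de_fac_loc=1.0, seed=7)
    cm, groups = simulate(params)
    return cm, groups


@pytest.fixture(scope="session")
def small_data(small_sim):
    cm, groups = small_sim
    return preprocess(cm), groups


@pytest.fixture(scope="session")
def two_blob():
    """Two 2-D Gaussian blobs, sigma 0.1, centers 4 apart."""
    rng = np.random.default_rng(0)
    n = 200
    labels = np.repeat([0, 1], n // 2)
    z = rng.normal(0.0, 0.1, size=(n, 2))
    z[labels == 1, 0] += 4.0
    return z, labels
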