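import numpy as np
import pytest

from contraclust import SimConfig, simulate


@pytest.fixture(scope="session")
def easy_dataset():
    """Well-separated 4-group dataset: strong DE factors, negligible dropout."""
    return simulate(
        SimConfig(
            group_sizes=[250] * 4,
            de_prob=0.1,
            de_fac_scale=0.5,
            dropout_mid=-10.0,
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, fast 3-group dataset for pipeline-level tests."""
    return simulate(
        SimConfig(
            n_genes=300,
            group_sizes=[40] * 3,
            de_prob=0.2,
            de_fac_scale=0.6,
            dropout_mid=-10.0,
            seed=1,
        )
    )


@pytest.fixture
def blob_embedding():
    """Two far-separated Gaussian blobs in 2-D with generating labels."""
    rng = np.random.default_rng(7)
    a = rng.normal([0, 0], 0.1, size=(20, 2))
    b = rng.normal([10, 10], 0.1, size=(20, 2))
    z = np.vstack([a, b])
    labels = np.array([0] * 20 + [1] * 20)
    return z, labels
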