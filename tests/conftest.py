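import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lncnet import SimConfig, generate_dataset
from lncnet.network import AdjacencyMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """Reference synthetic scenario: 5 planted modules x 100 genes, 50 noise
    genes, 60 samples over three periods."""
    return generate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 3-module scenario for pipeline-level tests."""
    cfg = SimConfig(
        n_modules=3,
        genes_per_module=60,
        n_noise_genes=30,
        n_asd_genes=20,
        seed=11,
    )
    return cfg, generate_dataset(cfg)


def random_adjacency(n: int, seed: int) -> AdjacencyMatrix:
    """Valid random unsigned adjacency (symmetric, [0,1], unit diagonal)."""
    rng = np.random.default_rng(seed)
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    ids = [f"g{i}" for i in range(n)]
    return AdjacencyMatrix(pd.DataFrame(a, index=ids, columns=ids))
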