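import numpy as np
import pytest
from hypothesis import settings

from metablup import CountTable, SimulationConfig, simulate_dataset

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """Synthetic dataset with moderate microbiome signal, shared across tests."""
    cfg = SimulationConfig(
        n_samples=60, m_contigs=300, n_causal=300, m2=0.5, seed=12345
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654)


@pytest.fixture()
def random_count_table(rng):
    def make(n=6, m=20, max_count=200, prefix="s"):
        return CountTable(
            sample_ids=[f"{prefix}{i}" for i in range(n)],
            feature_ids=[f"f{j}" for j in range(m)],
            counts=rng.integers(0, max_count, size=(n, m)),
        )

    return make
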