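import numpy as np
import pandas as pd
import pytest

from ldlmed import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort with planted effects, shared across tests."""
    cfg = SimulationConfig(n_samples=300, n_genes=300, seed=7)
    phenotypes, counts, truth = simulate_cohort(cfg)
    return cfg, phenotypes, counts, truth


@pytest.fixture
def toy_counts():
    """4 genes x 4 samples with hand-checkable CPMs (library sizes = 100)."""
    return pd.DataFrame(
        [[50, 50, 50, 50], [30, 30, 30, 0], [20, 20, 19, 50], [0, 0, 1, 0]],
        index=pd.Index([f"g{i}" for i in range(1, 5)], name="gene_id"),
        columns=[f"s{i}" for i in range(1, 5)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
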