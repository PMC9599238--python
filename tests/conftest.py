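import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ecosig.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """Small cohort with planted clusters, shared across unit tests."""
    config = SimConfig(
        n_samples=30,
        n_genes=60,
        n_signatures=4,
        n_clusters=3,
        genes_per_cluster=15,
        mutations_per_sample=5000,
        noise_sd=0.1,
        seed=42,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def noise_free_sim():
    """Cohort with zero expression/fraction noise: planted links are exact."""
    config = SimConfig(
        n_samples=30,
        n_genes=40,
        n_signatures=4,
        n_clusters=2,
        genes_per_cluster=10,
        mutations_per_sample=5000,
        noise_sd=0.0,
        fraction_noise_sd=0.0,
        bulk_poisson=False,
        seed=7,
    )
    return simulate_dataset(config)
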