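import pytest

from mycohet.config import SimulationConfig
from mycohet.synthetic_data import build_synthetic_dag, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A single-clade study small enough for per-test simulation."""
    return SimulationConfig(seed=7, n_genes=300, n_terms=60, n_clades=1).validate()


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_dag(small_config):
    return build_synthetic_dag(small_config)


@pytest.fixture(scope="session")
def noise_free_study():
    cfg = SimulationConfig.noise_free(seed=11, n_genes=250, n_terms=60, n_clades=1)
    return simulate_study(cfg)
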