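import numpy as np
import pytest

from ithlayers import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 3 H-like + 2 L-like patients, 3 regions each."""
    return SimulationConfig(
        n_patients_H=3,
        n_patients_L=2,
        n_mutations_mean=40,
        n_windows=60,
        n_genes=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
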