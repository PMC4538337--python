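import numpy as np
import pytest

from survmdr.dataset import SurvivalDataset
from survmdr.simulate import (PenetranceModel, SimulationConfig,
                              generate_penetrance, simulate_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture()
def tiny_data():
    """Six subjects, two SNPs, no covariates, one censored subject."""
    return SurvivalDataset(
        times=[2.0, 1.0, 3.0, 0.5, 4.0, 2.5],
        events=[1, 1, 0, 1, 1, 1],
        genotypes=[[0, 1], [1, 2], [2, 0], [0, 0], [1, 1], [2, 2]],
    )


@pytest.fixture(scope="session")
def easy_cohort():
    """A strongly detectable simulated cohort (no censoring)."""
    model = generate_penetrance(0.2, 0.3, seed=5)
    config = SimulationConfig(maf=0.2, h2=0.3, censor_prop=0.0)
    return simulate_dataset(model, config, np.random.default_rng(17))


@pytest.fixture(scope="session")
def censored_cohort():
    model = generate_penetrance(0.2, 0.2, seed=5)
    config = SimulationConfig(maf=0.2, h2=0.2, censor_prop=0.3)
    return simulate_dataset(model, config, np.random.default_rng(23))
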