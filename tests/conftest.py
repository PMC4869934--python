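import numpy as np
import pytest

from nfkbe2f import kinetics as kin
from nfkbe2f import synthetic_data as sd


@pytest.fixture(scope="session")
def base_model():
    return kin.build_model("base")


@pytest.fixture(scope="session")
def base_equilibrium(base_model):
    return kin.equilibrate(base_model)


@pytest.fixture(scope="session")
def base_trajectory(base_model, base_equilibrium):
    """Base model under sustained saturating TNFα, 600 min."""
    grid = np.arange(0.0, 601.0, 2.0)
    return kin.simulate_cell(base_model, base_equilibrium,
                             kin.StimulusProtocol(0.0, np.inf, 1.0), grid)


@pytest.fixture(scope="session")
def small_population():
    """Noiseless 30-cell treated population (shared across tests)."""
    cfg = sd.PopulationConfig(n_cells=30, seed=11, noise_sd=0.0)
    return cfg, sd.generate_population(cfg)


@pytest.fixture(scope="session")
def noisy_population():
    """Default-noise 30-cell treated population."""
    cfg = sd.PopulationConfig(n_cells=30, seed=13)
    return cfg, sd.generate_population(cfg)
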