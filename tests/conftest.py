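import numpy as np
import pytest

from rescuedip import ModelParams, SimulationConfig


@pytest.fixture(scope="session")
def defaults() -> ModelParams:
    """Baseline scenario: s_b=0.05, delta=0.01, s_d=0.001, mu=1e-5."""
    return ModelParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220439)


@pytest.fixture()
def quick_config() -> SimulationConfig:
    return SimulationConfig(replicates=200, seed=11)
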