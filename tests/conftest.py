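import pytest
from hypothesis import settings

from qfpcr.classifier import train
from qfpcr.panel import default_panel
from qfpcr.simulate import SimulationConfig, simulate_training_set

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def training_rows():
    """Small training table in the study's class balance."""
    return simulate_training_set(1500, 25, 25, seed=2024)


@pytest.fixture(scope="session")
def model(training_rows):
    """Classifier trained on the session training table."""
    return train(training_rows)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()
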