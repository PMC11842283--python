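import pytest

from sightkit import MediumSpec, STYRENE, VialSystem
from sightkit.vial_simulator import SimulationParams


@pytest.fixture
def styrene():
    return STYRENE


@pytest.fixture
def default_system():
    return VialSystem()


@pytest.fixture
def default_medium():
    return MediumSpec()


@pytest.fixture
def noiseless_params():
    return SimulationParams(noise_sd=0.0)
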