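"""Shared fixtures: synthetic cortices, sensor nets, gains (built once)."""

import numpy as np
import pytest

from harmony_eeg.bench import SimulationConfig, make_context
from harmony_eeg.forward import fibonacci_sensors
from harmony_eeg.geometry import make_two_hemisphere_space


@pytest.fixture(scope="session")
def space3():
    """Level-3 two-hemisphere pseudo-cortex (642 vertices per hemisphere)."""
    return make_two_hemisphere_space(3, seed=0)


@pytest.fixture(scope="session")
def space2():
    """Level-2 two-hemisphere pseudo-cortex (162 vertices per hemisphere)."""
    return make_two_hemisphere_space(2, seed=0)


@pytest.fixture(scope="session")
def sensors128():
    return fibonacci_sensors(128)


@pytest.fixture(scope="session")
def ctx3():
    """Level-3 bench context: meshes, 128 sensors, gain, noise covariance."""
    return make_context(SimulationConfig(mesh_level=3, seed=0))


@pytest.fixture(scope="session")
def ctx4():
    """Level-4 bench context (2,562 dipoles per hemisphere)."""
    return make_context(SimulationConfig(mesh_level=4, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
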