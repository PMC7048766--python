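import numpy as np
import pytest

from memvolt import (
    DEFAULT_CELL,
    MediumModel,
    SolverConfig,
    build_axisym_mesh,
    rectangular_waveform,
)

SIGMAS = (0.05, 0.1, 0.5)


@pytest.fixture(scope="session")
def cell():
    return DEFAULT_CELL


@pytest.fixture(scope="session")
def hepes():
    return MediumModel(0.05, label="HEPES")


@pytest.fixture(scope="session")
def coarse_config():
    """Reduced-resolution solver config for fast unit tests."""
    return SolverConfig(interface_edge_frac=0.05)


@pytest.fixture(scope="session")
def coarse_mesh(cell, coarse_config):
    return build_axisym_mesh(cell, coarse_config)


@pytest.fixture(scope="session")
def pulse_200ns():
    """8 kV/cm x 200 ns with a relaxation tail."""
    return rectangular_waveform(8e5, 200e-9, 1e-6)


@pytest.fixture(scope="session")
def pulse_100us():
    """1.2 kV/cm x 100 us with a relaxation tail."""
    return rectangular_waveform(1.2e5, 100e-6, 4e-6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
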