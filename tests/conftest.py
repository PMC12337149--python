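import numpy as np
import pytest

from gasbind.labeling import extract_events
from gasbind.synthetic import (
    ToySystem,
    label_toy_trajectory,
    simulate_ligand_diffusion,
)


@pytest.fixture(scope="session")
def toy_system():
    return ToySystem()


@pytest.fixture(scope="session")
def toy_trajectory(toy_system):
    """One medium-length run of the default toy system, reused across tests."""
    return simulate_ligand_diffusion(toy_system, n_ligands=30, n_frames=10000, seed=7)


@pytest.fixture(scope="session")
def toy_series(toy_trajectory):
    return label_toy_trajectory(toy_trajectory)


@pytest.fixture(scope="session")
def toy_events(toy_series):
    return [ev for s in toy_series for ev in extract_events(s, min_dwell=1)]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
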