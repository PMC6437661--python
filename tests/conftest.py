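import numpy as np
import pytest

from iemtools import (
    evenly_spaced_design,
    make_bimodal_transform,
    make_unimodal_basis,
    simulate_dataset,
    simulate_population,
    transform_basis,
)


@pytest.fixture(scope="session")
def design():
    """Default experiment: 8 evenly spaced orientations x 27 repeats (n=216)."""
    return evenly_spaced_design()


@pytest.fixture(scope="session")
def unimodal_basis():
    return make_unimodal_basis(8)


@pytest.fixture(scope="session")
def bimodal_basis(unimodal_basis):
    return transform_basis(unimodal_basis, make_bimodal_transform())


@pytest.fixture(scope="session")
def population():
    return simulate_population(v=100, m=180, h=40.0, seed=12345)


@pytest.fixture(scope="session")
def noiseless_data(population, design):
    train = simulate_dataset(population, design, 0.0, role="train")
    valid = simulate_dataset(population, design, 0.0, role="validation")
    return train, valid


@pytest.fixture(scope="session")
def noisy_data(population, design):
    train = simulate_dataset(population, design, 0.01, seed=7, role="train")
    valid = simulate_dataset(population, design, 0.01, seed=8, role="validation")
    return train, valid


@pytest.fixture
def rng():
    return np.random.default_rng(99)
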