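import numpy as np
import pytest

from polembed.fixtures import (
    make_dimer,
    make_model_qm_case,
    make_random_cluster,
    make_water_like_cluster,
)


@pytest.fixture(scope="session")
def random_cluster():
    """8-site multipolar cluster with chains and mixed polarizabilities."""
    return make_random_cluster(8, seed=42)


@pytest.fixture(scope="session")
def water_cluster():
    return make_water_like_cluster(3, seed=7)


@pytest.fixture(scope="session")
def model_case():
    """(MMSystem, ModelQM) coupled fixture with states S0, S1, SA."""
    return make_model_qm_case(seed=5)


@pytest.fixture()
def dimer():
    return make_dimer(separation=3.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
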