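import numpy as np
import pytest

from tcrm.energetics import EnergyModel
from tcrm.sidechain import RotamerLibrary
from tcrm.structio import partition_complex
from tcrm.synthetic import (SyntheticComplexSpec, TOY_CHAIN_MAP,
                            build_toy_complex, plant_clash_case)


@pytest.fixture(scope="session")
def em():
    return EnergyModel()


@pytest.fixture(scope="session")
def rotlib():
    return RotamerLibrary()


@pytest.fixture(scope="session")
def toy():
    """Default relaxed toy complex (62 deg crossing, 8 deg incident)."""
    model, truth = build_toy_complex(SyntheticComplexSpec(seed=1))
    return model, truth


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_partition(toy_model):
    return partition_complex(toy_model, TOY_CHAIN_MAP)[0]


@pytest.fixture(scope="session")
def clash_case():
    return plant_clash_case(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
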