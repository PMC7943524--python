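import numpy as np
import pytest

from marado.chem import parse_lipid_name
from marado.library import default_fatty_acid_pool, generate_library
from marado.simulate import (
    GroundTruthSpecies,
    SimulationConfig,
    simulate_dataset,
    standards_ground_truth,
)
from marado.standards import default_standards


@pytest.fixture(scope="session")
def pool():
    return default_fatty_acid_pool()


@pytest.fixture(scope="session")
def mar_library(pool):
    return generate_library(pool, ("Mar",), ("[M+FA-H]-",))


@pytest.fixture(scope="session")
def standards():
    return default_standards()


@pytest.fixture(scope="session")
def standards_dataset():
    """The ten authentic standards planted at their reference RT/CCS, seed 7."""
    config = SimulationConfig(seed=7)
    frames, features, manifest = simulate_dataset(standards_ground_truth(), config)
    return config, frames, features, manifest


@pytest.fixture(scope="session")
def single_species_dataset():
    """One isolated symmetric maradolipid, low noise, 20 eV."""
    species = [
        GroundTruthSpecies(
            parse_lipid_name("Mar(14:0/14:0)"), "[M+FA-H]-", 12.94, 284.40, 1000.0
        )
    ]
    config = SimulationConfig(seed=11)
    frames, features, manifest = simulate_dataset(species, config)
    return species, config, frames, features
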