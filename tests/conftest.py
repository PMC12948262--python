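import numpy as np
import pytest

from dualgraph_dta.model import ModelConfig, featurize_records
from dualgraph_dta.synthetic_data import (
    SyntheticConfig,
    SyntheticStructureProvider,
    generate_dataset,
    mock_atom_provider,
    mock_residue_provider,
)

REDUCED_ATOM_DIM = 16
REDUCED_RESIDUE_DIM = 32


@pytest.fixture(scope="session")
def atom_provider():
    return mock_atom_provider(dim=REDUCED_ATOM_DIM, seed=7)


@pytest.fixture(scope="session")
def residue_provider():
    return mock_residue_provider(dim=REDUCED_RESIDUE_DIM, seed=7)


@pytest.fixture(scope="session")
def structure_provider():
    return SyntheticStructureProvider(mode="random_walk", seed=7)


@pytest.fixture(scope="session")
def small_records():
    """80 planted-signal pairs, enough to train tiny models quickly."""
    return generate_dataset(SyntheticConfig(n_pairs=80, n_drugs=25, n_proteins=10,
                                            protein_length_range=(30, 60), seed=3))


@pytest.fixture(scope="session")
def small_dataset(small_records, atom_provider, residue_provider, structure_provider):
    return featurize_records(small_records, atom_provider, residue_provider,
                             structure_provider)


@pytest.fixture
def reduced_model_config():
    return ModelConfig.reduced(REDUCED_ATOM_DIM, REDUCED_RESIDUE_DIM)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
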