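import numpy as np
import pytest

from eraqsar import (
    PlantedSignalSpec,
    default_pattern_set,
    default_smiles_pool,
    generate_planted_dataset,
)


@pytest.fixture(scope="session")
def smiles_pool():
    return default_smiles_pool()


@pytest.fixture(scope="session")
def pattern_set():
    return default_pattern_set()


@pytest.fixture(scope="session")
def small_planted():
    """A fast, well-powered planted dataset shared by modelling tests."""
    spec = PlantedSignalSpec(
        n_compounds=200, n_features=40, n_informative=5,
        effect_sizes=[0.6] * 5, noise_sd=0.3, seed=1,
    )
    X, y, truth = generate_planted_dataset(spec)
    return spec, X, y, truth
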