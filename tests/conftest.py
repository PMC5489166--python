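import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from protloc.features_sequence import default_aaindex_table
from protloc.synthetic_data import GeneratorConfig, generate


@pytest.fixture(scope="session")
def aaindex():
    return default_aaindex_table()


@pytest.fixture(scope="session")
def small_proteome():
    """A small labeled synthetic proteome shared across read-only tests."""
    dataset, truth = generate(GeneratorConfig(n_proteins=40, seed=123))
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
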