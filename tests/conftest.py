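import numpy as np
import pytest

from songhmm.pomm import (
    example_song_pomm,
    null_label_chain,
    sample_dataset,
    stereotyped_chain_pomm,
)


@pytest.fixture(scope="session")
def example_pomm():
    """Six-state example grammar at the default (moderate) overlap."""
    return example_song_pomm()


@pytest.fixture(scope="session")
def example_pomm_full_overlap():
    """Example grammar with context-separable states acoustically merged."""
    return example_song_pomm(1.0)


@pytest.fixture(scope="session")
def chain_pomm():
    """Stereotyped 5-state first-order chain with separated emissions."""
    return stereotyped_chain_pomm()


@pytest.fixture(scope="session")
def null_chain():
    return null_label_chain()


@pytest.fixture(scope="session")
def example_train(example_pomm):
    return sample_dataset(example_pomm, n_bouts=30, max_len=100, seed=11)


@pytest.fixture(scope="session")
def chain_train(chain_pomm):
    return sample_dataset(chain_pomm, n_bouts=30, max_len=100, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
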