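from importlib import resources

import numpy as np
import pytest

from karyevo import SimConfig, make_ancestor, read_newick


@pytest.fixture(scope="session")
def species_tree():
    path = resources.files("karyevo.data").joinpath("species_tree.nwk")
    return read_newick(str(path))


@pytest.fixture(scope="session")
def default_ancestor():
    """Default study conditions: 8 chromosomes, 50 genes each."""
    genome, model = make_ancestor(SimConfig(seed=1))
    return genome, model


@pytest.fixture()
def ancestor(default_ancestor):
    genome, _ = default_ancestor
    return genome.copy()


@pytest.fixture()
def consensus_model(default_ancestor):
    return default_ancestor[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(17)
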