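import numpy as np
import pytest

from fragrl.a2c import TrainConfig
from fragrl.fixtures import generate_fixtures
from fragrl.fragmentation import build_fragment_library, pairwise_similarity
from fragrl.policy import TransformerParams
from fragrl.tree import build_balanced_tree


@pytest.fixture(scope="session")
def fixture_molecules():
    return generate_fixtures(20, seed=11, complexity="small").molecules


@pytest.fixture(scope="session")
def library(fixture_molecules):
    return build_fragment_library(fixture_molecules)


@pytest.fixture(scope="session")
def sim_matrix(library):
    return pairwise_similarity(library)


@pytest.fixture(scope="session")
def fragment_tree(library, sim_matrix):
    return build_balanced_tree(library, sim_matrix)


@pytest.fixture()
def tiny_params(library, fragment_tree):
    return TransformerParams(
        lib_size=len(library),
        code_len=fragment_tree.code_length,
        heads=2,
        blocks=1,
        d_f=16,
        d_p=8,
        head_layers=(32, 16),
        seed=7,
    )


@pytest.fixture()
def fast_cfg():
    return TrainConfig(time=1, epochs=3, batch_size=4, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
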