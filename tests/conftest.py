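import numpy as np
import pytest
from hypothesis import settings

from metamorphscan.foldclass import FoldClassLabel
from metamorphscan.synthetic import (
    StructureRecipe,
    build_beta_hairpin,
    build_ideal_helix,
    build_two_domain_decoy,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ideal_helix():
    return build_ideal_helix(20, seed=11)


@pytest.fixture(scope="session")
def ideal_hairpin():
    return build_beta_hairpin(8, seed=12)


@pytest.fixture(scope="session")
def decoy_alpha():
    return build_two_domain_decoy(StructureRecipe(FoldClassLabel.ALPHA, seed=21))


@pytest.fixture(scope="session")
def decoy_beta():
    return build_two_domain_decoy(StructureRecipe(FoldClassLabel.BETA, seed=22))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
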