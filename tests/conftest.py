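import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aptamap.constants import APTAMER_SEQUENCES
from aptamap.rna_mass import NEOMYCIN_B, RNASequence


@pytest.fixture(scope="session")
def rna2() -> RNASequence:
    return RNASequence(APTAMER_SEQUENCES["RNA2"], name="RNA2")


@pytest.fixture(scope="session")
def ligand():
    return NEOMYCIN_B


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
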