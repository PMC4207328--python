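import numpy as np
import pytest
from hypothesis import settings

from epistat import MarkerDef, fixture_tables

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixtures():
    return fixture_tables()


@pytest.fixture
def snp_pair():
    return MarkerDef("L1"), MarkerDef("L2")


@pytest.fixture
def binary_pair():
    return MarkerDef("A", "carrier_binary"), MarkerDef("B", "carrier_binary")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
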