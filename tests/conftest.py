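import numpy as np
import pytest

from olesuite.align import ScoringScheme
from olesuite.motif import olea_pattern


@pytest.fixture(scope="session")
def pattern():
    return olea_pattern()


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
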