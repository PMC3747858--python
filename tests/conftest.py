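import numpy as np
import pytest

from helpers import two_block_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture
def two_block():
    return two_block_matrix()
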