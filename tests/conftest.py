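import numpy as np
import pytest

from helpers import make_hypha_cell


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hypha_cell_factory():
    return make_hypha_cell
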