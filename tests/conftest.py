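import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_rng():
    def _make(seed=0):
        return np.random.default_rng(seed)

    return _make
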