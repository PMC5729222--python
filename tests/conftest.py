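import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from dmbc import make_toy_table


@pytest.fixture(scope="session")
def toy_table():
    return make_toy_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
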