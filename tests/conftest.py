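import numpy as np
import pytest

from peptopo.beta_pairing import toy_table
from peptopo.peptides import load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def toy():
    return toy_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
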