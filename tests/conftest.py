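import numpy as np
import pytest

from voctree import load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def model(fixtures):
    return fixtures.model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240506)
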