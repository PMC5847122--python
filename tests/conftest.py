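import numpy as np
import pytest

from prsdesign import make_scenario


@pytest.fixture(scope="session")
def cvd():
    return make_scenario("cvd")


@pytest.fixture(scope="session")
def breast_cancer():
    return make_scenario("breast_cancer")


@pytest.fixture(scope="session")
def height():
    return make_scenario("height")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
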