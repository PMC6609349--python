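import numpy as np
import pytest

from producibility import FeasibilitySolver, prepare_model
from producibility import synthetic


@pytest.fixture(scope="session")
def chain3():
    return synthetic.make_chain(3)


@pytest.fixture(scope="session")
def chain3_prep(chain3):
    return prepare_model(chain3)


@pytest.fixture(scope="session")
def chain3_solver(chain3_prep):
    return FeasibilitySolver(chain3_prep)


@pytest.fixture(scope="session")
def cofactor_prep():
    return prepare_model(synthetic.make_cofactor_loop(1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
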