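import numpy as np
import pytest

from mitosim import load_params, make_scenario


@pytest.fixture(scope="session")
def params():
    return load_params(None)


@pytest.fixture(scope="session")
def wt_scenario():
    return make_scenario("wild_type_cib", n_reps=4, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
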