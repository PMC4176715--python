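import copy

import numpy as np
import pytest

from crcea.fixtures import default_bundle, parameter_specs


@pytest.fixture(scope="session")
def bundle_I():
    return default_bundle("I")


@pytest.fixture(scope="session")
def bundle_II():
    return default_bundle("II")


@pytest.fixture()
def bundle_I_copy(bundle_I):
    """Mutable copy for tests that edit the model in place."""
    return copy.deepcopy(bundle_I)


@pytest.fixture(scope="session")
def outcomes_I(bundle_I):
    return bundle_I.run()


@pytest.fixture(scope="session")
def outcomes_II(bundle_II):
    return bundle_II.run()


@pytest.fixture(scope="session")
def params_I():
    return {p.name: p for p in parameter_specs("I")}


@pytest.fixture(scope="session")
def params_II():
    return {p.name: p for p in parameter_specs("II")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(8675309)
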