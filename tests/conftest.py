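import numpy as np
import pytest

from cowhemo import BloodProperties, build_cow_template
from cowhemo.params import GroupParamTable
from cowhemo.template import DEFAULT_INLET_VELOCITIES


@pytest.fixture(scope="session")
def blood():
    return BloodProperties()


@pytest.fixture()
def template_net():
    return build_cow_template()


@pytest.fixture(scope="session")
def default_velocities():
    return dict(DEFAULT_INLET_VELOCITIES)


@pytest.fixture(scope="session")
def params():
    return GroupParamTable.packaged()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
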