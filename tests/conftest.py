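import numpy as np
import pytest
from hypothesis import settings

from erfesim.params import load_parameters, load_pk_config

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return load_parameters("table1")


@pytest.fixture(scope="session")
def table2():
    return load_parameters("table2")


@pytest.fixture(scope="session")
def pk_config():
    return load_pk_config()


@pytest.fixture(scope="session")
def ckd_tiw_1350():
    """CKD t.i.w. 1350 IU/kg dose schedule (2 weeks)."""
    return tuple((float(t), 1350.0) for t in (0, 48, 96, 168, 216, 264))


@pytest.fixture
def rng():
    return np.random.default_rng(20240001)
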