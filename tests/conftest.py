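import numpy as np
import pytest

from megretest.cohort import CohortSpec, make_cohort
from megretest.forward import HeadModel, build_sensor_array


@pytest.fixture(scope="session")
def ctf_array():
    return build_sensor_array("ctf151")


@pytest.fixture(scope="session")
def vv_array():
    return build_sensor_array("vectorview306")


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_subjects=2, duration_s=30.0, seed=11)


@pytest.fixture(scope="session")
def fingerprints(small_spec):
    return make_cohort(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
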