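import numpy as np
import pytest

import recruitdemog as rd


@pytest.fixture(scope="session")
def scheme():
    return rd.default_scheme()


@pytest.fixture(scope="session")
def table1():
    return rd.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return rd.load_fixture("table2")


@pytest.fixture(scope="session")
def ref_params():
    return rd.reference_growth_params()


@pytest.fixture(scope="session")
def ref_matrix(ref_params):
    return rd.growth_matrix(ref_params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def cohort_vector(scheme, settlers=100.0):
    n0 = np.zeros(scheme.n_classes)
    n0[0] = settlers
    return n0


@pytest.fixture(scope="session")
def start100(scheme):
    return cohort_vector(scheme)
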