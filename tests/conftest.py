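import numpy as np
import pytest

from pedmets.synthetic import (CohortParams, make_reference_frame,
                               make_reference_tables, simulate_cohort)


@pytest.fixture(scope="session")
def default_params():
    return CohortParams()


@pytest.fixture(scope="session")
def reference_frame(default_params):
    return make_reference_frame(0, default_params)


@pytest.fixture(scope="session")
def references(default_params):
    return make_reference_tables(0, default_params)


@pytest.fixture(scope="session")
def bmi_ref(references):
    return references[0]


@pytest.fixture(scope="session")
def provider(references):
    return references[1]


@pytest.fixture(scope="session")
def cohort_124(default_params):
    return simulate_cohort(default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
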