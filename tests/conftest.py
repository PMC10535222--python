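import numpy as np
import pytest

from lumenvbe import formulation as fm
from lumenvbe import pbpk_core as pk
from lumenvbe import population as pop


@pytest.fixture(scope="session")
def drug():
    return pk.default_drug()


@pytest.fixture(scope="session")
def subject():
    return pk.default_subject()


@pytest.fixture(scope="session")
def reference():
    return fm.entocort_reference()


@pytest.fixture(scope="session")
def hv_population():
    return pop.default_healthy_population()


@pytest.fixture(scope="session")
def reference_result(drug, subject, reference):
    """Default representative-subject simulation, shared across tests."""
    model = pk.build_subject_model(drug, subject, reference, dose_mg=3.0)
    return pk.simulate_dose(model)


@pytest.fixture(scope="session")
def virtual_panel():
    return {f.label: f for f in fm.virtual_library()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20230830)
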