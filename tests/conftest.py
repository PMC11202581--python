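import numpy as np
import pytest
from hypothesis import settings

import msisig

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def id_signatures():
    return msisig.load_reference("ID83")


@pytest.fixture(scope="session")
def sbs_signatures():
    return msisig.load_reference("SBS96")


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort used across the suite."""
    return msisig.simulate_cohort(seed=20)


@pytest.fixture(scope="session")
def cohort_pipeline(cohort, id_signatures):
    """Cohort run through the full subtype pipeline."""
    catalog = msisig.build_id_catalog(cohort.records, cohort.reference)
    burden = msisig.compute_tmb(cohort.records, cohort.annotations)
    exposures = msisig.refit_exposures(catalog, id_signatures)
    calls = msisig.classify_cohort(burden, exposures, cohort.annotations)
    return dict(cohort=cohort, catalog=catalog, burden=burden,
                exposures=exposures, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
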