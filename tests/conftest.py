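import numpy as np
import pytest

from ccdnet import CohortConfig, build_parcellation, build_template, generate_cohort


@pytest.fixture(scope="session")
def parcellation():
    return build_parcellation()


@pytest.fixture(scope="session")
def normal_template(parcellation):
    return build_template(parcellation, "normal_cc", CohortConfig(rng_seed=0))


@pytest.fixture(scope="session")
def cohorts():
    """Default-condition cohorts at the default seed, shared across tests."""
    return {
        cond: generate_cohort(cond, CohortConfig(condition=cond, rng_seed=0))
        for cond in (
            "normal_cc",
            "complete_ccd",
            "partial_ccd",
            "virtual_callosotomy",
        )
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
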