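import numpy as np
import pytest

import postmeal as pm


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-participant cohort under the default study conditions."""
    return pm.simulate_cohort(pm.CohortSimConfig(n_participants=300, seed=7))


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    return pm.feature_table(small_cohort.curves)


@pytest.fixture(scope="session")
def clean_harmonized():
    """Harmonized instruments from a clean (no-pleiotropy) simulation."""
    exp, out = pm.simulate_two_sample_gwas(
        pm.MRSimConfig(n_snps=50, causal_beta=0.5, seed=2)
    )
    return pm.harmonize(exp, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
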