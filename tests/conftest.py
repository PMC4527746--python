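import pytest

from lohcna.pipeline import call_cohort
from lohcna.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale cohort: 75 samples, 5,000 probes, implanted aberrations."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_callset(default_cohort):
    callset, selection = call_cohort(default_cohort)
    return callset


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free cohort: zero CN noise and zero genotype error."""
    return generate_cohort(
        CohortConfig(cn_noise_sd=0.0, genotype_error_rate=0.0, seed=7))
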