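import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from sigcord import CohortConfig, ConcordanceAnalysis, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Compact cohort: default signature panel, trimmed background."""
    return CohortConfig(n_samples=300, n_background_genes=30, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def fitted(small_cohort):
    return ConcordanceAnalysis.from_cohort(small_cohort).fit()
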