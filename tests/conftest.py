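import pytest

from splicesig import CohortSimConfig, make_synthetic_target, simulate_cohort


@pytest.fixture(scope="session")
def target():
    """A 300-nt synthetic transcript with the 26-nt excision at position 150."""
    return make_synthetic_target(seed=11, length=300, junction_start=150,
                                 excision_length=26)


@pytest.fixture(scope="session")
def adverse_cohort():
    """Cohort in which the planted signature carries a log-hazard of 1."""
    return simulate_cohort(CohortSimConfig(seed=101))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose planted signature has no effect on survival."""
    return simulate_cohort(CohortSimConfig(effect_size=0.0, seed=202))
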