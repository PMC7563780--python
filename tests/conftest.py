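import pytest
from hypothesis import HealthCheck, settings

from melcohort.fixture import load_paper_fixture
from melcohort.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_cohort():
    """The pinned 82-patient reference cohort, loaded from package data."""
    return load_paper_fixture()


@pytest.fixture(scope="session")
def big_cohort():
    """A 10,000-patient simulated cohort for parameter-recovery checks."""
    return simulate_cohort(SimulationConfig(n_patients=10_000, seed=1234))
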