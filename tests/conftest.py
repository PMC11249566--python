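import numpy as np
import pytest

from dynrmtl import GompertzScenario, generate_cohort


@pytest.fixture(scope="session")
def default_scenario() -> GompertzScenario:
    """Printed two-exposure Gompertz scenario, 10% censoring, p=0.25."""
    return GompertzScenario(n=2000, censoring_rate=0.1, p_z1=0.25, p_z2=0.25)


@pytest.fixture(scope="session")
def cohort_2k(default_scenario):
    """One fixed 2000-subject cohort from the default scenario."""
    rng = np.random.default_rng(np.random.SeedSequence(1234))
    return generate_cohort(default_scenario, rng)


@pytest.fixture(scope="session")
def cohort_5k(default_scenario):
    """One fixed 5000-subject cohort (parameter-recovery checks)."""
    rng = np.random.default_rng(np.random.SeedSequence(99))
    return generate_cohort(default_scenario.with_(n=5000), rng)


@pytest.fixture(scope="session")
def uncensored_cohort_2k(default_scenario):
    """Censoring-free cohort: every weight must be exactly one."""
    rng = np.random.default_rng(np.random.SeedSequence(7))
    return generate_cohort(
        default_scenario.with_(censoring_rate=0.0), rng)
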