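import numpy as np
import pytest

import fallsim as fs


@pytest.fixture(scope="session")
def params():
    """Synthetic default parameter set, seed 1."""
    return fs.default_synthetic_parameters(1)


@pytest.fixture(scope="session")
def small_scenario():
    """Small, fast scenario shared by engine-level tests."""
    return fs.ScenarioConfig(
        strategy="UC", horizon_years=8, population_size=4_000,
        entry_cohort_size_per_cycle=100,
    )


@pytest.fixture(scope="session")
def paired_runs(params, small_scenario):
    """One paired UC/RC run on common random numbers (seed 11)."""
    uc = fs.run_strategy(params, small_scenario, 11)
    rc = fs.run_strategy(params, small_scenario.replace(strategy="RC"), 11)
    return uc, rc


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
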