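import pytest

from mitodx import SimulationConfig, run_cohort, simulate_cohort

#: Pinned seed of the default synthetic cohort used across the suite.
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic cohort: 48 cases / 48 controls, all nine planted
    causal mechanism classes, pinned seed."""
    return simulate_cohort(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def cohort_result(default_bundle):
    return run_cohort(default_bundle)


@pytest.fixture(scope="session")
def truth_by_patient(default_bundle):
    return {
        row["patient"]: row for row in default_bundle.truth.to_dict(orient="records")
    }
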