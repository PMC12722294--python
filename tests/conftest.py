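import pytest

from lscohort.scores import score_cohort
from lscohort.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort under the default study conditions."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    scored = score_cohort(default_cohort.frame)
    scored["male"] = (scored["sex"] == "male").astype(float)
    return scored


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort with an elevated event rate for fit-heavy tests."""
    cfg = SimulationConfig(seed=11, n=1500, baseline_rate_per_month=8e-4)
    scored = score_cohort(generate_cohort(cfg).frame)
    scored["male"] = (scored["sex"] == "male").astype(float)
    return scored
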