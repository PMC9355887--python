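import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sstlab as sl

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def session_config():
    return sl.SessionConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """3 x 3 subjects, full sessions; shared across fast tests."""
    spec = sl.CohortSpec(n_per_group=3)
    records, truth = sl.simulate_cohort(spec, sl.SessionConfig(), seed=7)
    return records, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study cohort (3 groups x 30 subjects), with its
    per-subject summary table; shared by the cohort-level tests."""
    spec = sl.CohortSpec()
    records, truth = sl.simulate_cohort(spec, sl.SessionConfig(), seed=1)
    summary = sl.summarize_cohort(records)
    return records, truth, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
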