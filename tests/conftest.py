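import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import briefmotion as bm
from briefmotion.fitting import ConditionCounts

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: generating parameters used by the recovery-style fixtures
TRUE_OBSERVER = bm.ObserverSpec(
    threshold_small=0.02, threshold_large=0.05, slope=0.15
)


def make_counts(observer, n_per_duration, seed, platform="CRT", durations=None):
    """Simulate binomial counts for both sizes from a parametric observer."""
    d = bm.make_duration_grid(7, 0.01, 0.2) if durations is None else durations
    rng = np.random.default_rng(seed)
    out = {}
    for size in ("small", "large"):
        p = bm.observer_prob_correct(observer, size, platform, d)
        k = rng.binomial(n_per_duration, p)
        out[size] = ConditionCounts(
            d, np.full(len(d), n_per_duration), k, key=("sim", platform, size)
        )
    return out


@pytest.fixture(scope="session")
def clean_counts():
    """Well-powered counts (n = 200/duration) from the reference observer."""
    return make_counts(TRUE_OBSERVER, 200, seed=11)


@pytest.fixture(scope="session")
def clean_fit(clean_counts):
    return bm.fit_conjoint(clean_counts["small"], clean_counts["large"])


@pytest.fixture(scope="session")
def small_study_trials():
    """A reduced 3-participant study for pipeline-level tests."""
    design = bm.DesignSpec(participants=3)
    plan = bm.build_trial_list(design, seed=21)
    cohort = bm.sample_cohort(TRUE_OBSERVER, 3, seed=22)
    return bm.simulate_trials(cohort, plan, seed=23)
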