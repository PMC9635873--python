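import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import reachcond as rc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp1_schedule():
    return rc.make_differential_schedule(600, 200, seed=11)


@pytest.fixture(scope="session")
def exp1_params():
    return rc.RWParams(**rc.EXP1_RW)


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 8-participant differential cohort (default study conditions)."""
    cfg = rc.SyntheticConfig(master_seed=101)
    return rc.generate_cohort("exp1_differential", 8, cfg)


@pytest.fixture(scope="session")
def small_cohort_pre(small_cohort):
    return [rc.preprocess(p) for p in small_cohort]


def random_differential_schedule(rng, n, design="exp1_differential"):
    """Unbalanced random CS/US schedule (acquisition only) for oracle tests."""
    trials = []
    for i in range(n):
        cue = "tone" if rng.random() < 0.5 else "light"
        trials.append(rc.Trial(
            index=i + 1, phase="acquisition", cs_set=frozenset({cue}),
            us=15.0 if cue == "tone" else 0.0,
        ))
    return rc.TrialSchedule(trials=trials, design=design, seed=0)
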