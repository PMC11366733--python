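import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import advisor_trust as at

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def design():
    return at.SessionDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def linear_participant(design, rng):
    """60 advice trials from a compromise w=0.5 participant, motor SD 0.5."""
    profile = at.StrategyProfile(kind="compromise", trust_weight=0.5)
    return at.simulate_advice_trials(60, profile, design, rng)


@pytest.fixture
def small_cohort(design):
    """Six participants with mixed strategies (fast to fit)."""
    profiles = [
        at.StrategyProfile(kind="compromise", trust_weight=0.7),
        at.StrategyProfile(kind="compromise", trust_weight=0.3),
        at.StrategyProfile(kind="adopt"),
        at.StrategyProfile(kind="self_doubt", trust_weight=0.1),
        at.StrategyProfile(kind="agent_doubt", trust_weight=1.0),
        at.StrategyProfile(kind="mixture", mixture_probs=(0.7, 0.3, 0.0)),
    ]
    return at.generate_cohort(6, profiles, design, seed=7)
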