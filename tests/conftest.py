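import logging

import pytest
from hypothesis import settings, HealthCheck

from cohortlink.config import CorruptionRates, SimConfig
from cohortlink.synthetic import simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("cohortlink").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clean_sim():
    """Small synthetic world with perfect identifiers."""
    config = SimConfig(n_persons=300, seed=42, corruption_rates=CorruptionRates.zero())
    persons, labs, diagnoses, roster, truth = simulate(config)
    return config, persons, labs, diagnoses, roster, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Small synthetic world with the default identifier corruption."""
    config = SimConfig(n_persons=300, seed=43)
    persons, labs, diagnoses, roster, truth = simulate(config)
    return config, persons, labs, diagnoses, roster, truth
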