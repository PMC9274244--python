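import datetime as dt

import pytest

from icees_lite import cohorts, synthetic
from icees_lite.model import StudyPeriod


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SynthConfig(n_patients=300, seed=7)


@pytest.fixture(scope="session")
def small_population(small_config):
    """One 300-patient synthetic cohort shared by read-only tests."""
    return synthetic.generate_population(small_config)


@pytest.fixture(scope="session")
def period_2020():
    return StudyPeriod(dt.date(2020, 1, 1), dt.date(2020, 12, 31))


@pytest.fixture(scope="session")
def outcome_spec(period_2020):
    return cohorts.OutcomeSpec(period=period_2020)
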