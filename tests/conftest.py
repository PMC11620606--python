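import pytest

from odontochron import crown_chronology, load_table1, make_cohort, simulate_tooth
from odontochron.synthetic import default_params


@pytest.fixture(scope="session")
def table1_records():
    return load_table1()


@pytest.fixture(scope="session")
def noiseless_tooth():
    """Default-parameter tooth with zero measurement noise."""
    return simulate_tooth(default_params(noise_cv=0.0, seed=1))


@pytest.fixture(scope="session")
def default_tooth():
    """Default-parameter tooth with 3% run-length noise."""
    return simulate_tooth(default_params(seed=1))


@pytest.fixture(scope="session")
def cohort20():
    """Study-condition cohort: 20 teeth at paper-centered defaults, seed 1."""
    return make_cohort(20, seed=1)


@pytest.fixture(scope="session")
def cohort20_results(cohort20):
    """Chronologies recovered from the cohort, paired with their truths."""
    return [(crown_chronology(sec), truth) for sec, truth in cohort20]
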