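import pytest

from tdabc_cea import config as cfgmod
from tdabc_cea.synthetic import (
    STENTING_PHASES,
    fixture_soc_phases,
    fixture_stenting_log,
    fixture_stenting_rates,
)
from tdabc_cea.tdabc import roll_up


@pytest.fixture(scope="session")
def base_config():
    return cfgmod.base_case()


@pytest.fixture(scope="session")
def stenting_breakdown():
    """Roll-up of the noiseless stenting fixture log."""
    return roll_up(fixture_stenting_log(), fixture_stenting_rates(), STENTING_PHASES)


@pytest.fixture(scope="session")
def soc_episode():
    """Outpatient conservative-care episode, 3 active months."""
    return fixture_soc_phases(months_active=3)
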