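import pytest

from hbpkit import EconomyParams, default_economy, malawi_fixture, malawi_reference


@pytest.fixture(scope="session")
def malawi():
    return malawi_fixture()


@pytest.fixture(scope="session")
def econ():
    return default_economy()


@pytest.fixture(scope="session")
def reference():
    return malawi_reference()


@pytest.fixture
def plain_econ():
    return EconomyParams(k_usd_per_daly=61.0)
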