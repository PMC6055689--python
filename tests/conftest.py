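import pytest

from mimorank import wildtype_region
from mimorank.fixtures import GOLDEN_SHORTLIST
from mimorank.scoring import default_conversion_table


@pytest.fixture(scope="session")
def wildtype():
    return wildtype_region()


@pytest.fixture(scope="session")
def golden_rows():
    return GOLDEN_SHORTLIST


@pytest.fixture(scope="session")
def conversion_table():
    return default_conversion_table()
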