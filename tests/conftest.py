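import pytest

from scrkit.genetic_code import STANDARD_CODE
from scrkit.library_design import agg_screening_library
from scrkit.mass_analysis import ResidueMassTable


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def agg_spec():
    """The packaged anticodon-binding-domain library spec."""
    return agg_screening_library()


@pytest.fixture(scope="session")
def mass_table():
    return ResidueMassTable()
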