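import pytest

from hcomb import load_table
from hcomb.synthetic import fixture_molecules


@pytest.fixture(scope="session")
def table():
    return load_table()


@pytest.fixture(scope="session")
def fixtures():
    return fixture_molecules()
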