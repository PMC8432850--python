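import pytest

from icd2iss import synthetic


@pytest.fixture(scope="session")
def rules():
    return synthetic.default_rules()


@pytest.fixture(scope="session")
def policies():
    return synthetic.default_policies()


@pytest.fixture(scope="session")
def detail_map():
    return synthetic.default_detail_map()


@pytest.fixture(scope="session")
def ais_table():
    return synthetic.default_ais_table()
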