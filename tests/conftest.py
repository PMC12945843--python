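import pytest

from hspscreen import ChiContext, cefdinir_molar_volume, load_group_table, load_reference_substances


@pytest.fixture(scope="session")
def fixture():
    return load_reference_substances()


@pytest.fixture(scope="session")
def table():
    return load_group_table()


@pytest.fixture(scope="session")
def chi_context(table):
    return ChiContext(drug_molar_volume=cefdinir_molar_volume(table))
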