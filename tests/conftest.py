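import pytest

from equity_synth import synth_data


@pytest.fixture(scope="session")
def table3_groups():
    return synth_data.table3_fixture()


@pytest.fixture(scope="session")
def table3_by_label(table3_groups):
    return {g.label: g for g in table3_groups}


@pytest.fixture(scope="session")
def table3_summary():
    return synth_data.table3_printed_summary()


@pytest.fixture(scope="session")
def table4_scenarios():
    return synth_data.table4_fixture()


@pytest.fixture(scope="session")
def uk_distribution():
    return synth_data.default_uk_distribution()
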