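import pytest

from nbs_dualscreen import fixtures


@pytest.fixture(scope="session")
def table3():
    return fixtures.load_table3()


@pytest.fixture(scope="session")
def table3_panel():
    return fixtures.table3_panel()


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_table2()


@pytest.fixture(scope="session")
def table1():
    return fixtures.load_table1()
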