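import pytest

from fetchstats import design_for, paper_fixture


@pytest.fixture(scope="session")
def fixture_map():
    return paper_fixture()


@pytest.fixture(scope="session")
def exp1_design():
    return design_for("exp1")


@pytest.fixture(scope="session")
def exp2_design():
    return design_for("exp2")


@pytest.fixture(scope="session")
def exp3_design():
    return design_for("exp3")
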