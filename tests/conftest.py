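import pytest

from dietshift import load_romania_fixture


@pytest.fixture(scope="session")
def romania():
    """The bundled Romanian 2021 inputs: basket, mix, population, references."""
    return load_romania_fixture()


@pytest.fixture(scope="session")
def basket(romania):
    return romania[0]


@pytest.fixture(scope="session")
def mix(romania):
    return romania[1]


@pytest.fixture(scope="session")
def population(romania):
    return romania[2]


@pytest.fixture(scope="session")
def references(romania):
    return romania[3]
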