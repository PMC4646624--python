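import pytest

from lakeweb.synth import fixture_suite


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture
def chain3(fixtures):
    return fixtures["chain3"]


@pytest.fixture
def minilake(fixtures):
    return fixtures["minilake"]
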