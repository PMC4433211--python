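import pytest

from cagemap import make_fixture, run_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_result(tiny_fixture):
    return run_fixture(tiny_fixture)
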