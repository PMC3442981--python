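import pytest

from budstrain import default_environment, make_pyrcore


@pytest.fixture(scope="session")
def pyrcore():
    return make_pyrcore()


@pytest.fixture(scope="session")
def env():
    """Glucose uptake 10, oxygen uptake 2, ATP maintenance 1 (mmol/gDCW/h)."""
    return default_environment()
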