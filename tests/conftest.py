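import pytest

from mitosoma.caller import CallerConfig
from mitosoma.haplogroups import default_library
from mitosoma.reference import load_reference


@pytest.fixture(scope="session")
def model():
    return load_reference()


@pytest.fixture(scope="session")
def library(model):
    return default_library(model)


@pytest.fixture(scope="session")
def caller_config():
    return CallerConfig()
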