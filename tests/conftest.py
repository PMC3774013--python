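import pytest

from va2012.standard import (
    load_cause_list,
    load_constants,
    load_indicator_registry,
    load_subsumption_map,
)


@pytest.fixture(scope="session")
def cause_list():
    return load_cause_list()


@pytest.fixture(scope="session")
def registry():
    return load_indicator_registry()


@pytest.fixture(scope="session")
def constants():
    return load_constants()


@pytest.fixture(scope="session")
def subsumption(cause_list):
    return load_subsumption_map(cause_list=cause_list)
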