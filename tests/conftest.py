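import pytest

from boolrd.examples import (
    double_toggle_chain,
    emt_core_network,
    emt_profiles,
    negative_two_ring,
    parallel_toggles,
    toggle_switch,
)


@pytest.fixture
def toggle():
    return toggle_switch()


@pytest.fixture
def neg_ring():
    return negative_two_ring()


@pytest.fixture
def emt():
    return emt_core_network()


@pytest.fixture
def emt_prof():
    return emt_profiles()


@pytest.fixture
def chained_toggles():
    return double_toggle_chain()


@pytest.fixture
def independent_toggles():
    return parallel_toggles()
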