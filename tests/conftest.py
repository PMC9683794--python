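import pytest

from polyshift.config import make_lande_preset, make_non_lande_preset


@pytest.fixture(scope="session")
def lande_preset():
    return make_lande_preset(shift_in_sd=4.0)


@pytest.fixture(scope="session")
def nonlande_preset():
    return make_non_lande_preset(shift_in_sd=4.0)
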