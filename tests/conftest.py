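import pytest
from hypothesis import settings

from conefund import compute_fundamentals, standard_observer

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fund2():
    """Standard 2-deg energy fundamentals on the default 390-830 @ 1 nm grid."""
    return compute_fundamentals(standard_observer("deg2"))


@pytest.fixture(scope="session")
def fund10():
    return compute_fundamentals(standard_observer("deg10"))


@pytest.fixture(scope="session")
def fund2_quantal():
    return compute_fundamentals(standard_observer("deg2"), units="quantal")
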