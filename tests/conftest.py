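import pytest

from telekin import RateParams

# Printed operating points used throughout: the strongly repressed
# reference operator, and the slow/fast pair sharing one mean.
OSYM = dict(r=24.6, gamma=0.79, k_a=9.79, k_d=0.10)
SLOW = dict(r=25.0, gamma=0.8, k_a=3.0, k_d=0.18)
FAST = dict(r=25.0, gamma=0.8, k_a=30.0, k_d=1.8)


@pytest.fixture
def osym_params() -> RateParams:
    return RateParams(**OSYM)


@pytest.fixture
def slow_params() -> RateParams:
    return RateParams(**SLOW)


@pytest.fixture
def fast_params() -> RateParams:
    return RateParams(**FAST)
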