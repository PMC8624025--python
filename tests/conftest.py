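import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20211105)


@pytest.fixture
def small_phantom_spec():
    """A fast 120×90 phantom at default noise levels."""
    from hemitherm import PhantomSpec

    return PhantomSpec(height=120, width=90, seed=7)
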