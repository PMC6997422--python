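import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hb_small(rng):
    """A small, fast 'hemoglobin-like' dataset: N(14, 0.98), n=1500, 1 decimal."""
    from ksref import validate_dataset

    values = rng.normal(14.0, 0.98, size=1500)
    return validate_dataset(values, decimals=1)
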