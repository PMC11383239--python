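import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def std_views(rng):
    """A pair of standardised random views with shared rows."""
    from stabcca import standardize_matrix

    X = rng.standard_normal((20, 5))
    Y = rng.standard_normal((20, 8))
    Y[:, 0] += 0.7 * X[:, 0]
    return standardize_matrix(X), standardize_matrix(Y)
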