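import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# Derandomised hypothesis runs so the suite is reproducible everywhere.
settings.register_profile(
    "rallyflux",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("rallyflux")


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
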