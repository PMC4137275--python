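import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ct_times():
    """The circadian sampling grid: CT18..CT64, every 2 h."""
    return 18.0 + 2.0 * np.arange(24)
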