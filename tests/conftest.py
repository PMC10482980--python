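import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from punishmpt.model import FrequencyTable, ParameterVector, expected_counts

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def theta_interior() -> ParameterVector:
    """An interior parameter vector with realistic punishment rates."""
    return ParameterVector(0.6, 0.4, 0.2, 0.1, 0.1)


@pytest.fixture
def saturated_table() -> tuple[ParameterVector, FrequencyTable]:
    """A table whose counts equal the expected counts under a known theta.

    With theta = (0.5, 0.5, 0, 0, 0.5) and 80 trials per tree every expected
    count is an integer, so the model can reproduce the table exactly.
    """
    theta = ParameterVector(0.5, 0.5, 0.0, 0.0, 0.5)
    counts = expected_counts(theta, 80, 80)
    assert np.allclose(counts, np.round(counts))
    return theta, FrequencyTable(counts.astype(int))
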