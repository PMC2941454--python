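import pytest
from hypothesis import settings

from crbsi_cea import PERSPECTIVES, calibrate, default_parameters

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    """Calibrated default parameters, shared across the suite."""
    return calibrate(default_parameters())


@pytest.fixture(scope="session")
def baseline():
    return PERSPECTIVES["baseline"]
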