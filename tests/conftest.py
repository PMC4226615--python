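import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import mitostrand as m


@pytest.fixture(scope="session")
def demo_ref():
    return m.mtdna_demo_reference(seed=0)


@pytest.fixture(scope="session")
def toy_ref():
    """2 kb balanced-composition circular genome."""
    return m.generate_reference(2000, [("AC", 0.5, 2000)], seed=11, name="toy")
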