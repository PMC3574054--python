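import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import headingbias as hb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profile_1s_13cm():
    """The standard translation stimulus: 1 s, 13 cm."""
    return hb.make_motion_profile(1.0, 0.13)


@pytest.fixture(scope="session")
def design():
    """Default identification design: 48 headings x 5 blocks x 2 reps."""
    return hb.IdentificationDesign()


@pytest.fixture(scope="session")
def headings_48(design):
    return np.asarray(design.headings_deg, dtype=float)
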