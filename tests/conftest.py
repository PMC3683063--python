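import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shulk.kinetics import MonodParams

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# Printed anaerobic generation-time summaries (mean, se, n) for the three
# focal strains, used as test inputs throughout.
ANAEROBIC_SUMMARIES = {
    "EDM106": (56.50, 0.30, 3),
    "EDM116": (50.97, 0.32, 3),
    "EDM530": (49.03, 0.24, 3),
}

# Carrying-capacity worked example (dry weight g/30ml) for the coexisting pair.
CAPACITIES = {"K1": 19.9, "K2": 21.6, "K_co": 21.8, "p1": 0.55}


@pytest.fixture
def shulk_pair():
    """An sHULK pair: a is the exploiter (high mu_max), b the gleaner (low K_s)."""
    return MonodParams(mu_max=1.0, K_s=1.0), MonodParams(mu_max=0.7, K_s=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
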