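import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config():
    from forkslip.synthetic import SimConfig

    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def reference(sim_config):
    """Default synthetic reference ORF with its planted repeat pairs."""
    from forkslip.synthetic import generate_reference, rng_for

    seq, placements = generate_reference(
        sim_config, rng_for(sim_config.seed, "reference"), return_placements=True
    )
    return seq, placements
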