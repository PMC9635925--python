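import logging

import pytest
from hypothesis import HealthCheck, settings

import mrgscreen as ms

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

logging.getLogger("mrgscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def reference_hits():
    """The packaged 34-compound reference hit table."""
    return ms.load_reference_hits()


@pytest.fixture(scope="session")
def reference_library():
    return ms.reference_hit_library()


@pytest.fixture(scope="session")
def small_screen():
    """A compact two-plate screen (704 compounds, triplicate, both genotypes)."""
    cfg = ms.SimulationConfig(n_compounds=704, seed=11)
    plates, truth = ms.simulate_screen(cfg)
    return cfg, plates, truth
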