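import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def qc_config():
    from qpcrval import default_qc_config

    return default_qc_config()


@pytest.fixture
def sim_config():
    from qpcrval import SimulationConfig

    return SimulationConfig(seed=7)


@pytest.fixture
def small_plate(sim_config):
    """One simulated dilution-series plate for a single target."""
    from qpcrval import AssayTarget, simulate_dilution_series

    return simulate_dilution_series(sim_config, AssayTarget.BRAF_V600)
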