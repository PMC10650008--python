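import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nirs_vispercept as nv

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def optics():
    return nv.MBLLConfig()


@pytest.fixture(scope="session")
def sim_config():
    return nv.SimulationConfig(seed=3)


@pytest.fixture(scope="session")
def schedule(sim_config):
    return nv.build_protocol(sim_config, seed=3)


@pytest.fixture(scope="session")
def hemoglobin(schedule, sim_config):
    return nv.simulate_hemodynamics(schedule, sim_config, seed=3)


@pytest.fixture(scope="session")
def per_stage_windows(hemoglobin, schedule):
    """Normalized per-stage windows of one filtered session."""
    filtered = nv.bandpass(hemoglobin)
    return nv.segment_windows(
        nv.normalize_series(filtered), schedule, mode="per_stage", participant="p00"
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
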