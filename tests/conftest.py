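import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from satlib import SatConsensus, simulate_library

settings.register_profile(
    "satlib",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("satlib")


@pytest.fixture(scope="session")
def consensus() -> SatConsensus:
    """A fixed 177-nt satellite consensus used across the suite."""
    lib = simulate_library(1, 177, 0.0, seed=20230)
    return SatConsensus("SimSat01-177", lib.sequences[0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
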