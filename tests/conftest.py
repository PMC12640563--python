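import numpy as np
import pytest
from hypothesis import settings

from chromwalk.digest import EnzymeSpec
from chromwalk.simulate import SimConfig, simulate

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dpnii() -> EnzymeSpec:
    return EnzymeSpec("DpnII", "GATC", 0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """A mixed simulation reused across read-only tests."""
    cfg = SimConfig(seed=42, n_read_pairs=300, fraction_sv_junctions=0.3)
    return simulate(cfg)
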