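import numpy as np
import pytest

from melanosim.geometry import DomainSpec, build_tissue
from melanosim.simulator import SimulationConfig


@pytest.fixture(scope="session")
def small_tissue():
    """~50-cell tiling of a 100 um square."""
    return build_tissue(DomainSpec(100.0, 50, seed=0))


@pytest.fixture(scope="session")
def unit_tissue():
    """The degenerate single-Kc tiling: one square polygon."""
    return build_tissue(DomainSpec(1.0, 1))


@pytest.fixture(scope="session")
def medium_tissue():
    """~600-cell tiling, large enough for population dynamics."""
    return build_tissue(DomainSpec(250.0, 620, seed=1))


@pytest.fixture
def small_config():
    """A fast simulation configuration on the medium tissue scale."""
    return SimulationConfig(
        domain=DomainSpec(250.0, 620, seed=1),
        n_mbs=40,
        warmup_steps=5,
        recorded_steps=15,
        seed=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
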