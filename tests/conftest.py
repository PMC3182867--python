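from dataclasses import replace

import numpy as np
import pytest

from swarmtaxis.dynamics import MotionParams
from swarmtaxis.experiments import SimulationConfig, default_config
from swarmtaxis.interactions import InteractionZones, WeightPolicy
from swarmtaxis.terrain import TerrainParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bowl_terrain():
    """Purely radial concentration bowl (no periodic obstacles)."""
    return TerrainParams(periodic_amplitude=0.0)


@pytest.fixture
def small_config():
    """A fast, small simulation configuration for unit tests."""
    cfg = default_config()
    return replace(
        cfg,
        n_agents=6,
        max_steps=300,
        start_position=(-3.1, 0.7),
    )


@pytest.fixture
def zones():
    return InteractionZones(repulsion=0.5, orientation=1.0, attraction=2.0)
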