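import numpy as np
import pytest

from glucoville.agents import PlayerPolicyParams
from glucoville.dynamics import PhysiologyParams
from glucoville.world import GameConfig


@pytest.fixture
def config():
    return GameConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phys():
    """A mid-range T2D-like physiology used across dynamics tests."""
    return PhysiologyParams(
        basal_glucose=8.0,
        insulin_sensitivity=3.5,
        endogenous_secretion=0.5,
        insulin_resistance=2.0,
        renal_impaired=False,
    )


@pytest.fixture
def t1d_phys():
    return PhysiologyParams(
        basal_glucose=8.0,
        insulin_sensitivity=3.5,
        endogenous_secretion=0.0,
        insulin_resistance=1.0,
        renal_impaired=False,
    )


@pytest.fixture
def player():
    return PlayerPolicyParams(skill=0.5)
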