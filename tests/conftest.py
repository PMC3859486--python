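import numpy as np
import pytest

from hiersim import AbilitySpec, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, fast configuration exercising every phase."""
    return SimConfig(
        n=16,
        l=4,
        p=0.1,
        k=2,
        capacity_low=1,
        capacity_high=3,
        ability_spec=AbilitySpec(family="bounded_pareto"),
        rounds=40,
        seed=7,
        compute_forward=False,
    )
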