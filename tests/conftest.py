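import numpy as np
import pytest

from sptlock import synthetic as syn


@pytest.fixture
def free_scenario():
    """Moderate free-diffusion scenario: monomers, all labeled in A."""
    return syn.SimScenario(
        n_frames=100,
        density=0.3,
        fov=(15.0, 15.0),
        p_label=1.0,
        color_split=1.0,
        loc_noise_sigma=0.020,
        seed=42,
    )


@pytest.fixture
def trapped_scenario():
    """Two-state scenario with long dwell times in 35 nm domains."""
    trap = syn.TrapModel(
        p_arrest=0.02, p_release=0.02, domain_diameter=0.035, d_trap=0.002
    )
    return syn.SimScenario(
        n_frames=500,
        density=0.2,
        fov=(15.0, 15.0),
        p_label=1.0,
        color_split=1.0,
        trap=trap,
        loc_noise_sigma=0.020,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
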