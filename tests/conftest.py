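import numpy as np
import pytest

from invertype.damage import profile_damage
from invertype.synth import (SimulationConfig, make_panel, simulate_specimen,
                             strong_differentiation_frequencies)


@pytest.fixture(scope="session")
def strong_freqs():
    return strong_differentiation_frequencies()


@pytest.fixture(scope="session")
def small_panel():
    """Four inversions x 25 sites."""
    return make_panel(25, seed=11)


@pytest.fixture(scope="session")
def damage_sim(strong_freqs):
    """One heavily sequenced damaged specimen: ~2e5 observations.

    Simulated with d0=0.25, lambda=0.3, e=0.01 and the default lognormal
    fragment model; shared by the damage-recovery tests.
    """
    panel = make_panel(100, seed=21)
    cfg = SimulationConfig(coverage_mean=500.0, error_rate=0.01,
                           damage_amplitude=0.25, damage_decay=0.3, seed=77)
    rng = np.random.default_rng(77)
    truth, obs = simulate_specimen("DMG0", "NEAC", panel, strong_freqs, cfg,
                                   rng=rng)
    assert len(obs) > 150_000
    return panel, cfg, truth, obs


@pytest.fixture(scope="session")
def damage_profile_fixture(damage_sim):
    panel, cfg, truth, obs = damage_sim
    return profile_damage(obs, panel)
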