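import numpy as np
import pytest

from sosswitch import SimulationConfig, simulate_mother_machine

LN2 = np.log(2.0)


@pytest.fixture(scope="session")
def damage_free_sim():
    """Mother-machine run without switching: pure low-state growth."""
    cfg = SimulationConfig(alpha=0.0, lambda1=LN2, duration=24.0,
                           n_lineages=100, frame_interval=12.0, seed=5)
    return simulate_mother_machine(cfg)


@pytest.fixture(scope="session")
def switching_sim():
    """Mother-machine run with switching and an instantaneous GFP jump."""
    cfg = SimulationConfig(alpha=0.05, lambda1=LN2, duration=20.0,
                           n_lineages=600, frame_interval=12.0,
                           gfp_rise_time=0.0, seed=7)
    return simulate_mother_machine(cfg)
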