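import numpy as np
import pytest

from acemin import MineralizationContext, SimulationConfig


@pytest.fixture
def ctx() -> MineralizationContext:
    """Default mass-balance constants: 30 mM DIC, 1 mM acetate, n = 2."""
    return MineralizationContext()


@pytest.fixture
def biphasic_cfg() -> SimulationConfig:
    """Noise-free biphasic replicate with all breakpoints on integer days.

    Oxygen inventory 400 μM caps the aerobic phase at 200 μM acetate
    (reached on day 2 at 100 μM/d); the sulfidogenic phase runs from day 10
    at 20 μM/d and exhausts the substrate on day 50.
    """
    return SimulationConfig(
        o2_uM=400.0,
        phase1_rate_uM_per_d=100.0,
        lag_d=8.0,
        phase2_rate_uM_per_d=20.0,
        sulfide_yield=0.9,
        noise_sd_delta_permil=0.0,
        noise_sd_sulfide_uM=0.0,
        seed=1,
    )


@pytest.fixture
def biphasic_grid() -> np.ndarray:
    return np.array(sorted({0.0, 1.0} | set(np.arange(2.0, 50.5, 2.0))))
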