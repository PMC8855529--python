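"""Shared fixtures: small, fast scenario runs reused across test modules."""

import numpy as np
import pytest

from gammasync import SimulationConfig, build_scenario, run


@pytest.fixture(scope="session")
def small_ei_result():
    """A reduced sparse EI two-network run (scenario-3 wiring, 60 E + 16 I
    per network) long enough for the measures pipeline to operate."""
    spec = build_scenario(3, N_E=60, N_I=16, sigma2=0.7, p_ratio=0.85,
                          seed=11)
    cfg = SimulationConfig(dt=0.1, duration=1500.0, transient_discard=300.0,
                           seed=11)
    return run(spec, cfg)


@pytest.fixture(scope="session")
def small_ing_result():
    """A reduced all-to-all ING two-network run (120 I per network)."""
    spec = build_scenario(1, N_I=120, sigma2=0.5, p_ratio=0.85,
                          J_ppii=0.15, seed=5)
    cfg = SimulationConfig(dt=0.5, duration=1500.0, transient_discard=300.0,
                           seed=5)
    return run(spec, cfg)
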