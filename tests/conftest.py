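import numpy as np
import pytest

from rbc_oxyshear.flow import (
    Channel,
    FlowProblem,
    PulseProfile,
    Tube,
    solve_pulsatile,
    solve_steady,
)
from rbc_oxyshear.rheology import CassonParams


@pytest.fixture(scope="session")
def newtonian_params():
    """Effectively Newtonian blood-plasma stand-in: vanishing yield stress."""
    return CassonParams(hct=1e-9, mu0=3.5e-3, mu_cap=None)


@pytest.fixture(scope="session")
def steady_channel_field():
    """Steady Casson channel solution shared across mapping tests."""
    problem = FlowProblem(inlet=0.3, nx=16, ny=64)
    return solve_steady(problem)


@pytest.fixture(scope="session")
def small_pulsatile_result():
    """Coarse pulsatile channel run (fast) for per-phase contracts."""
    problem = FlowProblem(
        geometry=Channel(), inlet=PulseProfile(), nx=32, ny=32, n_store=10
    )
    return solve_pulsatile(problem), problem
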