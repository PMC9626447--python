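"""Shared fixtures: baseline parameter sets and reference trajectories.

The 12-h deterministic trajectories at dt = 1e-2 s are session-scoped;
several tests read different aspects of the same physics (oscillation
extrema, timing, boundedness, regime classification) so they share one
integration each.
"""

import pytest

from linecell import tables
from linecell.model_core import REC, TEC, UEC
from linecell.simulator import CellState, SimulationConfig, simulate

HOURS_12 = 43200.0


@pytest.fixture(scope="session")
def params():
    return {label: tables.phenotype_parameters(label)
            for label in (REC, UEC, TEC)}


def _initial(p):
    a0, L0, c0 = tables.default_initial_conditions(p)
    return CellState(t=0.0, a=a0, L=L0, c=c0)


@pytest.fixture(scope="session")
def initial_states(params):
    return {label: _initial(p) for label, p in params.items()}


@pytest.fixture(scope="session")
def traj_12h(params, initial_states):
    """Deterministic 12-h trajectories, dt = 1e-2 s, recorded every 2 s."""
    cfg = SimulationConfig(dt=1e-2, T=HOURS_12, stochastic=False,
                           record_every=200)
    return {label: simulate(params[label], initial_states[label], cfg)
            for label in (REC, UEC, TEC)}
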