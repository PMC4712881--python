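"""Shared fixtures.

The expensive full-scale runs used by the acceptance suite are
session-scoped so each configuration is simulated exactly once.
"""

import numpy as np
import pytest

from germsim import initialize, preset, run_simulation, step


@pytest.fixture(scope="session")
def short_run():
    """A small larval run (16 -> 22 hph) for cheap integration checks."""
    config = preset("default", seed=7)
    state = initialize(config)
    while state.clock_hph < 22.0:
        step(state)
    return state


@pytest.fixture(scope="session")
def adult_run():
    """Default preset run to t_end with cell tracking; used by the
    homeostasis, reversal, conservation and stretch-comparison checks."""
    config = preset("default", seed=3)
    config.run.track_trajectories = True
    return run_simulation(config, metrics_every=1.0)


@pytest.fixture(scope="session")
def no_stretch_run():
    """The no-stretch + DTC-pausing scenario with the same seed as
    adult_run, stopped once gonadogenesis is over."""
    config = preset("no_stretch_pausing", seed=3)
    return run_simulation(config, until=40.0, metrics_every=1.0)
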