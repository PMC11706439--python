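"""Shared fixtures.

The expensive closed-loop runs and Sobol sweeps are session-scoped so that
the acceptance checks and property tests share a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import baroloop as bl
from baroloop.sensitivity import run_gsa

#: fixed seed for every stochastic fixture in the suite
SUITE_SEED = 101


@pytest.fixture(scope="session")
def reg1():
    return bl.default_parameters("1ch", True)


@pytest.fixture(scope="session")
def unreg1():
    return bl.default_parameters("1ch", False)


@pytest.fixture(scope="session")
def reg4():
    return bl.default_parameters("4ch", True)


@pytest.fixture(scope="session")
def unreg4():
    return bl.default_parameters("4ch", False)


@pytest.fixture(scope="session")
def reg1_traj(reg1):
    """Regulated one-chamber run to steady state (protocol conditions)."""
    return bl.simulate(reg1, bl.SimulationConfig(t_end=150.0))


@pytest.fixture(scope="session")
def reg4_traj(reg4):
    """Regulated four-chamber run to steady state (protocol conditions)."""
    return bl.simulate(reg4, bl.SimulationConfig(t_end=300.0))


@pytest.fixture(scope="session")
def equivalent_unreg1(reg1):
    """Equivalent unregulated one-chamber model per the comparison protocol."""
    eq, overrides = bl.derive_unregulated_equivalent(
        reg1, bl.SimulationConfig(t_end=150.0))
    return eq, overrides


@pytest.fixture(scope="session")
def unreg1_gsa_2048(equivalent_unreg1):
    """Sobol GSA of the equivalent unregulated 1CH model, K=2048."""
    eq, _ = equivalent_unreg1
    return run_gsa(eq, k=2048, n_boot=100, seed=SUITE_SEED, dt=2e-3)


@pytest.fixture(scope="session")
def unreg1_gsa_128(equivalent_unreg1):
    """Matched reduced-K unregulated GSA for the damping comparison."""
    eq, _ = equivalent_unreg1
    return run_gsa(eq, k=128, n_boot=50, seed=SUITE_SEED, dt=2e-3)


@pytest.fixture(scope="session")
def reg1_gsa_128(reg1):
    """Scaled-down Sobol GSA of the regulated 1CH model (36 parameters)."""
    return run_gsa(reg1, k=128, n_boot=50, seed=SUITE_SEED, dt=4e-3)


@pytest.fixture(scope="session")
def reg1_lsa(reg1):
    """Local sensitivity of the regulated 1CH model (36 x 10)."""
    from baroloop.sensitivity import local_sensitivity
    return local_sensitivity(reg1, bl.SimulationConfig(t_end=100.0, dt=2e-3))


@pytest.fixture(scope="session")
def unreg1_lsa(equivalent_unreg1):
    """Local sensitivity of the equivalent unregulated 1CH model (9 x 9)."""
    from baroloop.sensitivity import local_sensitivity
    eq, _ = equivalent_unreg1
    return local_sensitivity(eq, bl.SimulationConfig(t_end=60.0, dt=2e-3))


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
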