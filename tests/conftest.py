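"""Shared fixtures: the calibrated parameter set and cached simulations.

Simulations are the expensive part of the suite, so trajectories are
computed once per session at dt = 0.02 h (well inside the integrator's
convergence regime) and shared across tests; tests that probe the
committed dt = 0.01 h behavior run their own simulations.
"""

from __future__ import annotations

from functools import lru_cache

import pytest

from frqclock import (
    constant,
    default_discard,
    default_parameters,
    simulate,
    symmetric_ld,
)

SIM_DT = 0.02


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def dd_trajectory(params):
    """600 h constant-darkness run of the calibrated wild type."""
    return simulate(params, constant(0.0), 600.0, dt=SIM_DT)


@pytest.fixture(scope="session")
def ld_trajectory(params):
    """Factory for cached symmetric-LD runs: ld_trajectory(half_period)."""

    @lru_cache(maxsize=None)
    def _run(half_period: float, n_cycles: int = 20):
        protocol = symmetric_ld(half_period, 1.0)
        discard = default_discard(protocol)
        t_end = discard + max(n_cycles * protocol.T, 240.0)
        return simulate(params, protocol, t_end, dt=SIM_DT)

    return _run
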