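"""Shared fixtures: ideal ensembles and a small Theta-condition MD run.

Everything is generated at test time from fixed seeds; the session scope
keeps the expensive ensembles to one generation per run.
"""

import numpy as np
import pytest

import polysesans as ps


@pytest.fixture(scope="session")
def ideal_ensemble():
    """2000 ideal chains of 150 beads, b = 1 (single frame)."""
    return ps.sample_ideal_ensemble(chains=2000, beads=150, b=1.0, seed=42)


@pytest.fixture(scope="session")
def ideal_ensemble_large():
    """1e4 ideal chains of 100 beads for Monte-Carlo density checks."""
    return ps.sample_ideal_ensemble(chains=10_000, beads=100, b=1.0, seed=43)


@pytest.fixture(scope="session")
def md_ensemble_small():
    """Short dilute Theta-condition bead-spring run: 4 chains x 60 beads.

    40k equilibration + 60k production steps; enough bead-steps (1.4e7)
    for thermostat statistics, small enough to run in seconds.
    """
    cfg = ps.MDConfig(seed=11, schedule=ps.Schedule(40_000, 60_000, 1_000))
    initial = ps.build_initial_ensemble(4, 60, seed=12)
    return ps.run_langevin(cfg, initial)


@pytest.fixture
def rg15():
    return ps.GaussianChainModel(Rg=15.0, N=100)


@pytest.fixture
def rg1():
    return ps.GaussianChainModel(Rg=1.0, N=100)


def abel_quadrature(func, z, upper=np.inf):
    """Independent Abel-projection oracle: singularity-free u-substituted
    adaptive quadrature, used to validate the closed-form G0."""
    from scipy import integrate

    val, _ = integrate.quad(
        lambda u: func(np.hypot(u, z)), 0.0, upper, limit=800, epsabs=1e-13, epsrel=1e-12
    )
    return 2.0 * val
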