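"""Shared fixtures: small seeded Monte-Carlo systems reused across modules.

Session-scoped so the statistically heavier trajectories (the two-particle
Boltzmann check, the dilute TI/Widom pair) are sampled once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import hydrosolv as hs


@pytest.fixture(scope="session")
def ideal_gas_traj() -> hs.Trajectory:
    """Non-interacting ternary mixture (all eps=0, q=0): the homogeneous
    reference for g(r)=1 and Gamma(r)=0 checks."""
    s = hs.ParticleSpecies("S", 0.0, 0.0)
    c = hs.ParticleSpecies("C", 0.0, 0.0)
    w = hs.ParticleSpecies("W", 0.0, 0.0)
    top = hs.Topology.from_counts({s: 5, c: 60, w: 200})
    comp = hs.SystemComposition({"S": 5, "C": 60, "W": 200}, 30.0, 298.15)
    return hs.run_nvt(comp, top, n_sweeps=2000, seed=11, step_size=0.5, stride=5)


@pytest.fixture(scope="session")
def lj_pair_system():
    """Two distinct LJ particles in a 2 nm box: species, topology, composition."""
    a = hs.ParticleSpecies("A", 0.30, 0.60)
    b = hs.ParticleSpecies("B", 0.30, 0.60)
    top = hs.Topology.from_molecules([[a], [b]])
    comp = hs.SystemComposition({"A": 1, "B": 1}, 20.0, 298.15)
    return a, b, top, comp


@pytest.fixture(scope="session")
def lj_pair_traj(lj_pair_system) -> hs.Trajectory:
    """Long two-particle LJ run for Boltzmann-distribution and dilute-PMF checks."""
    _, _, top, comp = lj_pair_system
    return hs.run_nvt(
        comp, top, n_sweeps=60000, seed=5, step_size=0.35, stride=5
    )


@pytest.fixture(scope="session")
def dilute_bath():
    """Sparse LJ bath (30 particles, 2.5 nm box) and an LJ solute species."""
    bath_sp = hs.ParticleSpecies("B", 0.3151, 0.6364)
    solute_sp = hs.ParticleSpecies("S", 0.3905, 0.4937)
    return bath_sp, solute_sp


@pytest.fixture(scope="session")
def ti_states(dilute_bath):
    """Lambda series for one LJ solute in the sparse bath (11 lambda points)."""
    bath_sp, solute_sp = dilute_bath
    top = hs.Topology.from_molecules([[solute_sp]] + [[bath_sp]] * 30)
    comp = hs.SystemComposition({"S": 1, "B": 30}, 25.0, 298.15)
    grid = np.linspace(0.0, 1.0, 11)
    return hs.run_lambda_series(
        comp, top, solute_molecule=0, lambda_grid=grid,
        n_sweeps=900, seed=23, step_size=0.3, stride=5,
    )


@pytest.fixture(scope="session")
def bath_only_traj(dilute_bath) -> hs.Trajectory:
    """The bare bath (no solute) for Widom test-particle insertion."""
    bath_sp, _ = dilute_bath
    top = hs.Topology.from_counts({bath_sp: 30})
    comp = hs.SystemComposition({"B": 30}, 25.0, 298.15)
    return hs.run_nvt(comp, top, n_sweeps=2500, seed=29, step_size=0.3, stride=10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
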