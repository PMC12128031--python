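"""Seedable NVT Metropolis Monte-Carlo engine for periodic LJ(+charge) mixtures.

The engine samples the canonical ensemble of a mixture of rigid molecules in
a cubic periodic box with pairwise-additive nonbonded interactions

    U_ij(r) = 4*eps_ij*[(sig_ij/r)^12 - (sig_ij/r)^6] + k_e*q_i*q_j/r

between sites of *different* molecules, with Lorentz-Berthelot combining,
a single-range cutoff (default 1.2 nm) and, inside the sampler, a
truncated-and-shifted LJ so that move energies are continuous at the cutoff.
Moves are rigid whole-molecule translations accepted with the Metropolis
rule min(1, exp(-dU/kBT)).  Identical seeds and inputs give bit-identical
trajectories.

A linearly lambda-coupled variant scales all interactions of one tagged
solute molecule by (1-lambda) — lambda=0 fully interacting, lambda=1 ideal —
and records dV/dlambda = -U_solute samples for thermodynamic integration.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import COULOMB_K, KB
from .model import (
    Frame,
    InitializationError,
    LambdaState,
    OverlapError,
    ParticleSpecies,
    SystemComposition,
    Topology,
    Trajectory,
    minimum_image,
    wrap_positions,
)

#: Interacting site pairs closer than this fraction of sigma_ij are treated
#: as unphysical overlaps by the public energy routines.
OVERLAP_FRACTION = 0.1

DEFAULT_CUTOFF = 1.2  # nm, mirrors a 12.2 Å single-range cutoff at toy scale


def combine_lorentz_berthelot(
    species_i: ParticleSpecies, species_j: ParticleSpecies
) -> tuple[float, float]:
    """Lorentz-Berthelot combining: arithmetic sigma, geometric epsilon."""
    sigma_ij = 0.5 * (species_i.sigma + species_j.sigma)
    epsilon_ij = math.sqrt(species_i.epsilon * species_j.epsilon)
    return sigma_ij, epsilon_ij


def pair_energy(
    r_ij: float,
    sigma_ij: float,
    epsilon_ij: float,
    q_i: float = 0.0,
    q_j: float = 0.0,
    cutoff: float = DEFAULT_CUTOFF,
    shift: bool = False,
) -> float:
    """Site-site nonbonded energy at separation ``r_ij`` (nm), in kJ/mol.

    Plain truncation by default: the full LJ + Coulomb value for
    ``r_ij <= cutoff`` and exactly 0 beyond.  With ``shift=True`` the LJ part
    is shifted so it vanishes continuously at the cutoff (the convention the
    Monte-Carlo engine samples with); the Coulomb part is always plain
    truncated.
    """
    if r_ij <= 0:
        raise OverlapError(f"non-positive site separation r={r_ij}")
    if r_ij > cutoff:
        return 0.0
    u = 0.0
    if epsilon_ij > 0 and sigma_ij > 0:
        s6 = (sigma_ij / r_ij) ** 6
        u += 4.0 * epsilon_ij * (s6 * s6 - s6)
        if shift:
            sc6 = (sigma_ij / cutoff) ** 6
            u -= 4.0 * epsilon_ij * (sc6 * sc6 - sc6)
    if q_i != 0.0 and q_j != 0.0:
        u += COULOMB_K * q_i * q_j / r_ij
    return u


def total_energy(
    frame: Frame,
    topology: Topology,
    cutoff: float = DEFAULT_CUTOFF,
    shift: bool = False,
    overlap_check: bool = True,
) -> float:
    """Sum of pair energies over all intermolecular site pairs, minimum image.

    Intramolecular pairs are excluded.  Interacting pairs closer than
    ``OVERLAP_FRACTION * sigma_ij`` raise :class:`OverlapError` unless
    ``overlap_check`` is disabled.
    """
    pos = frame.positions
    n = pos.shape[0]
    if n != topology.n_sites:
        raise ValueError("frame does not match topology")
    if n < 2:
        return 0.0
    sig = topology.array("sigma")
    eps = topology.array("epsilon")
    q = topology.array("charge")
    mol = topology.molecule_ids
    iu, ju = np.triu_indices(n, k=1)
    inter = mol[iu] != mol[ju]
    iu, ju = iu[inter], ju[inter]
    d = minimum_image(pos[iu] - pos[ju], frame.box)
    r = np.sqrt((d * d).sum(axis=1))
    sij = 0.5 * (sig[iu] + sig[ju])
    eij = np.sqrt(eps[iu] * eps[ju])
    if overlap_check:
        interacting = (eij > 0) | ((q[iu] != 0) & (q[ju] != 0))
        bad = interacting & (r < OVERLAP_FRACTION * sij)
        if np.any(bad):
            k = int(np.flatnonzero(bad)[0])
            raise OverlapError(
                f"sites {iu[k]} and {ju[k]} overlap: r={r[k]:.4g} nm < "
                f"{OVERLAP_FRACTION:.2f}*sigma_ij={OVERLAP_FRACTION * sij[k]:.4g} nm"
            )
    within = r <= cutoff
    r, sij, eij = r[within], sij[within], eij[within]
    qq = q[iu][within] * q[ju][within]
    r = np.maximum(r, 1e-12)
    u = np.zeros_like(r)
    lj = (eij > 0) & (sij > 0)
    if np.any(lj):
        s6 = (sij[lj] / r[lj]) ** 6
        u[lj] = 4.0 * eij[lj] * (s6 * s6 - s6)
        if shift:
            sc6 = (sij[lj] / cutoff) ** 6
            u[lj] -= 4.0 * eij[lj] * (sc6 * sc6 - sc6)
    u += np.where(qq != 0.0, COULOMB_K * qq / r, 0.0)
    return float(u.sum())


class _Engine:
    """Internal incremental-energy Metropolis sampler.

    Keeps per-site parameter arrays and a running total energy; a move
    recomputes only the moved molecule's interactions with the rest of the
    system.  Optional linear lambda coupling scales every interaction that
    involves the tagged solute molecule by (1 - lambda).
    """

    def __init__(
        self,
        topology: Topology,
        box: float,
        temperature: float,
        cutoff: float = DEFAULT_CUTOFF,
        lam: float = 0.0,
        solute_molecule: int | None = None,
        rng: np.random.Generator | None = None,
        step_size: float = 0.05,
    ) -> None:
        self.top = topology
        self.box = float(box)
        self.beta = 1.0 / (KB * temperature)
        self.cutoff = min(cutoff, self.box / 2.0)
        self.cutoff2 = self.cutoff**2
        self.lam = float(lam)
        self.solute_molecule = solute_molecule
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.step = float(step_size)

        self.sig = topology.array("sigma")
        self.half_sig = 0.5 * self.sig
        self.sqrteps = np.sqrt(topology.array("epsilon"))
        self.q = topology.array("charge")
        self.mol = topology.molecule_ids
        self.mol_sites = topology.molecule_sites()
        self.n_mol = len(self.mol_sites)
        self.has_charges = bool(np.any(self.q != 0.0))
        # static complement index lists: sites outside each molecule
        self._others = [np.flatnonzero(self.mol != m) for m in range(self.n_mol)]
        self.noninteracting = bool(
            np.all(self.sqrteps == 0.0) and np.all(self.q == 0.0)
        )
        self.pos: np.ndarray | None = None
        self.energy = 0.0
        self.accepted = 0
        self.attempted = 0

    # -- energy ------------------------------------------------------------
    def _site_energy(self, i: int, ri: np.ndarray, exclude_mol: int) -> float:
        """Shifted-LJ + truncated-Coulomb energy of site i at position ri
        against all sites outside molecule ``exclude_mol``; lambda-weighted."""
        idx = self._others[exclude_mol]
        d = self.pos[idx] - ri
        d -= self.box * np.round(d / self.box)
        r2 = np.einsum("ij,ij->i", d, d)
        close = r2 <= self.cutoff2
        if not close.any():
            return 0.0
        j = idx[close]
        r2c = np.maximum(r2[close], 1e-24)
        sij = self.half_sig[i] + self.half_sig[j]
        eij = self.sqrteps[i] * self.sqrteps[j]
        s2 = sij * sij
        s6 = (s2 / r2c) ** 3
        sc6 = (s2 / self.cutoff2) ** 3  # sij = 0 contributes exactly 0
        u = 4.0 * eij * ((s6 * s6 - s6) - (sc6 * sc6 - sc6))
        if self.has_charges:
            qq = self.q[i] * self.q[j]
            nz = qq != 0.0
            if np.any(nz):
                u[nz] += COULOMB_K * qq[nz] / np.sqrt(r2c[nz])
        if self.lam != 0.0 and self.solute_molecule is not None:
            # Pairs involving the tagged solute are scaled by (1 - lambda).
            if exclude_mol == self.solute_molecule:
                u *= 1.0 - self.lam
            else:
                sol = self.mol[j] == self.solute_molecule
                u[sol] *= 1.0 - self.lam
        return float(u.sum())

    def molecule_energy(self, m: int, positions: np.ndarray) -> float:
        return sum(
            self._site_energy(int(i), positions[k], m)
            for k, i in enumerate(self.mol_sites[m])
        )

    def solute_interaction_energy(self) -> float:
        """Full-coupling interaction energy of the tagged solute with the
        environment (the lambda derivative is its negative)."""
        if self.solute_molecule is None:
            return 0.0
        m = self.solute_molecule
        lam_saved, self.lam = self.lam, 0.0
        try:
            return self.molecule_energy(m, self.pos[self.mol_sites[m]])
        finally:
            self.lam = lam_saved

    def recompute_total(self) -> float:
        self.energy = 0.5 * sum(
            self.molecule_energy(m, self.pos[self.mol_sites[m]])
            for m in range(self.n_mol)
        )
        return self.energy

    # -- initial placement -------------------------------------------------
    def place_random(self, max_tries: int = 2000) -> None:
        """Random sequential insertion with a hard-core overlap veto."""
        n = self.top.n_sites
        self.pos = np.zeros((n, 3))
        placed: list[int] = []
        for m in range(self.n_mol):
            sites = self.mol_sites[m]
            ok = False
            for _ in range(max_tries):
                origin = self.rng.uniform(0.0, self.box, size=3)
                trial = wrap_positions(origin[None, :] + np.zeros((sites.size, 3)), self.box)
                if self._placement_ok(sites, trial, placed):
                    self.pos[sites] = trial
                    ok = True
                    break
            if not ok:
                raise InitializationError(
                    f"could not place molecule {m} after {max_tries} tries"
                )
            placed.extend(int(s) for s in sites)
        if not self.noninteracting:
            self.recompute_total()

    def _placement_ok(
        self, sites: np.ndarray, trial: np.ndarray, placed: list[int]
    ) -> bool:
        if not placed or self.noninteracting:
            return True
        others = np.asarray(placed)
        for k, i in enumerate(sites):
            d = minimum_image(self.pos[others] - trial[k], self.box)
            r2 = np.einsum("ij,ij->i", d, d)
            sij = 0.5 * (self.sig[int(i)] + self.sig[others])
            # allow soft placement at 0.85 sigma; MC relaxes the rest
            if np.any(r2 < (0.85 * sij) ** 2):
                return False
        return True

    # -- sampling ----------------------------------------------------------
    def sweep(self) -> None:
        """One sweep: n_mol attempted rigid-translation moves."""
        if self.noninteracting:
            # Ideal system: every move is accepted; vectorise the sweep.
            disp = self.rng.uniform(-self.step, self.step, size=(self.n_mol, 3))
            for m in range(self.n_mol):
                self.pos[self.mol_sites[m]] = wrap_positions(
                    self.pos[self.mol_sites[m]] + disp[m], self.box
                )
            self.accepted += self.n_mol
            self.attempted += self.n_mol
            return
        for _ in range(self.n_mol):
            m = int(self.rng.integers(self.n_mol))
            sites = self.mol_sites[m]
            old = self.pos[sites].copy()
            disp = self.rng.uniform(-self.step, self.step, size=3)
            new = wrap_positions(old + disp, self.box)
            u_old = self.molecule_energy(m, old)
            self.pos[sites] = new
            u_new = self.molecule_energy(m, new)
            du = u_new - u_old
            self.attempted += 1
            if du <= 0.0 or self.rng.random() < math.exp(-self.beta * du):
                self.energy += du
                self.accepted += 1
            else:
                self.pos[sites] = old

    def tune_step(self, target: float = 0.4) -> None:
        if self.attempted == 0:
            return
        rate = self.accepted / self.attempted
        if rate > target + 0.05:
            self.step = min(self.step * 1.1, self.box / 2.0)
        elif rate < target - 0.05:
            self.step = max(self.step * 0.9, 1e-4)
        self.accepted = 0
        self.attempted = 0


def _build_engine(
    composition: SystemComposition,
    topology: Topology,
    seed: int,
    step_size: float,
    cutoff: float,
    lam: float = 0.0,
    solute_molecule: int | None = None,
) -> _Engine:
    if composition.n_total != topology.n_molecules:
        raise ValueError(
            f"composition lists {composition.n_total} molecules but topology "
            f"has {topology.n_molecules}"
        )
    if any(sites.size != 1 for sites in topology.molecule_sites()):
        # Rigid multi-site molecules are representable in the data model but
        # the sampler only generates single-site (united-atom style) systems.
        raise ValueError("the Monte-Carlo engine samples single-site molecules only")
    rng = np.random.default_rng(seed)
    eng = _Engine(
        topology,
        composition.box_nm,
        composition.temperature,
        cutoff=cutoff,
        lam=lam,
        solute_molecule=solute_molecule,
        rng=rng,
        step_size=step_size,
    )
    eng.place_random()
    return eng


def run_nvt(
    composition: SystemComposition,
    topology: Topology,
    n_sweeps: int = 2000,
    seed: int = 0,
    step_size: float = 0.05,
    stride: int = 10,
    cutoff: float = DEFAULT_CUTOFF,
    equilibration_fraction: float = 0.2,
) -> Trajectory:
    """Sample an NVT trajectory by Metropolis Monte Carlo.

    The first ``equilibration_fraction`` of the sweeps is discarded; during
    it the maximum displacement is auto-tuned toward ~40% acceptance and then
    frozen.  Frames are recorded every ``stride`` production sweeps.
    Identical inputs and seed give bit-identical trajectories.
    """
    eng = _build_engine(composition, topology, seed, step_size, cutoff)
    n_equil = int(round(equilibration_fraction * n_sweeps))
    frames: list[Frame] = []
    for s in range(n_sweeps):
        eng.sweep()
        if s < n_equil:
            if (s + 1) % 50 == 0:
                eng.tune_step()
            continue
        if (s - n_equil) % stride == 0:
            frames.append(Frame(eng.pos.copy(), eng.box, step=s))
    return Trajectory(
        topology, frames, composition.temperature, seed=seed, stride=stride
    )


def run_lambda_series(
    composition: SystemComposition,
    topology: Topology,
    solute_molecule: int,
    lambda_grid: np.ndarray,
    n_sweeps: int = 2000,
    seed: int = 0,
    step_size: float = 0.05,
    stride: int = 5,
    cutoff: float = DEFAULT_CUTOFF,
    equilibration_fraction: float = 0.2,
) -> list[LambdaState]:
    """Sample dV/dlambda in the lambda-coupled ensemble at each grid point.

    The coupling is strictly linear, V(lam) = (1-lam) V0 + lam V1 with the
    tagged solute molecule non-interacting in state 1, so
    dV/dlambda = V1 - V0 = -U_solute evaluated at full coupling.  Each lambda
    gets an independent, seed-derived stream; the default 21-point equispaced
    grid is the caller's responsibility.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(np.diff(lambda_grid) < 0):
        raise ValueError("lambda grid must be sorted ascending")
    if np.any((lambda_grid < 0) | (lambda_grid > 1)):
        raise ValueError("lambda grid must lie in [0, 1]")
    if not (0 <= solute_molecule < topology.n_molecules):
        raise ValueError("solute molecule index out of range")

    states: list[LambdaState] = []
    n_equil = int(round(equilibration_fraction * n_sweeps))
    for k, lam in enumerate(lambda_grid):
        eng = _build_engine(
            composition,
            topology,
            np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31),
            step_size,
            cutoff,
            lam=float(lam),
            solute_molecule=solute_molecule,
        )
        samples: list[float] = []
        for s in range(n_sweeps):
            eng.sweep()
            if s < n_equil:
                if (s + 1) % 50 == 0:
                    eng.tune_step()
                continue
            if (s - n_equil) % stride == 0:
                samples.append(-eng.solute_interaction_energy())
        states.append(LambdaState(float(lam), np.asarray(samples)))
    return states
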