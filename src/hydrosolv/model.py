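"""Core data model: species, topologies, compositions, frames, trajectories.

The model mirrors a minimal force-field description of a multi-species
particle mixture in a cubic periodic box: every site carries Lennard-Jones
parameters (sigma, epsilon), a partial charge and a mass, and belongs to
exactly one molecule.  The Monte-Carlo engine moves molecules rigidly, so
single-site molecules are the common case, but the grouping is retained so
that multi-site rigid molecules (e.g. an idealised diatomic probe) can be
represented and analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_NM


class HydrosolvError(Exception):
    """Base class for package errors."""


class OverlapError(HydrosolvError):
    """Two interacting sites are unphysically close (or coincident)."""


class InitializationError(HydrosolvError):
    """Random placement of the requested composition failed."""


@dataclass(frozen=True)
class ParticleSpecies:
    """A site type: LJ well parameters, partial charge and mass.

    Parameters
    ----------
    name:
        Label used in trajectory files and selections.
    sigma:
        LJ zero-crossing distance in nm (``sigma >= 0``; 0 means no LJ core).
    epsilon:
        LJ well depth in kJ/mol (``epsilon >= 0``).
    charge:
        Partial charge in elementary charges.
    mass:
        Site mass in amu (``mass > 0``); used for centre-of-mass selections.
    """

    name: str
    sigma: float
    epsilon: float
    charge: float = 0.0
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.mass <= 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")


@dataclass
class Topology:
    """Ordered sites grouped into molecules.

    ``species`` holds one :class:`ParticleSpecies` per site, ``molecule_ids``
    the (0-based, contiguous) molecule index of each site.
    """

    species: list[ParticleSpecies]
    molecule_ids: np.ndarray

    def __post_init__(self) -> None:
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.intp)
        if len(self.species) != self.molecule_ids.size:
            raise ValueError("species list and molecule_ids length mismatch")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_molecules(cls, molecules: list[list[ParticleSpecies]]) -> "Topology":
        """Build a topology from a list of molecules (lists of species)."""
        species: list[ParticleSpecies] = []
        mol_ids: list[int] = []
        for m, sites in enumerate(molecules):
            if not sites:
                raise ValueError("empty molecule in topology")
            species.extend(sites)
            mol_ids.extend([m] * len(sites))
        return cls(species, np.asarray(mol_ids, dtype=np.intp))

    @classmethod
    def from_counts(cls, counts: dict[ParticleSpecies, int]) -> "Topology":
        """Single-site molecules: ``counts[sp]`` molecules of each species."""
        molecules = [[sp] for sp, n in counts.items() for _ in range(n)]
        return cls.from_molecules(molecules)

    # -- derived views -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.species)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_ids.max()) + 1 if self.n_sites else 0

    @property
    def labels(self) -> list[str]:
        return [sp.name for sp in self.species]

    def array(self, attr: str) -> np.ndarray:
        """Per-site array of a species attribute ('sigma', 'epsilon', ...)."""
        return np.asarray([getattr(sp, attr) for sp in self.species], dtype=float)

    def molecule_sites(self) -> list[np.ndarray]:
        """Site index arrays, one per molecule, in molecule-id order."""
        order = np.argsort(self.molecule_ids, kind="stable")
        ids = self.molecule_ids[order]
        cuts = np.flatnonzero(np.diff(ids)) + 1
        return [np.asarray(g) for g in np.split(order, cuts)]

    def species_table(self) -> dict[str, ParticleSpecies]:
        table: dict[str, ParticleSpecies] = {}
        for sp in self.species:
            prev = table.setdefault(sp.name, sp)
            if prev != sp:
                raise ValueError(f"conflicting parameters for species {sp.name!r}")
        return table


@dataclass
class SystemComposition:
    """Species counts, cubic box edge and temperature of one system.

    The box edge is given in Å, following the convention of composition
    tables; use :attr:`box_nm` everywhere downstream.
    """

    counts: dict[str, int]
    box_edge: float  # Å
    temperature: float  # K

    def __post_init__(self) -> None:
        for name, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {name!r}")
        if self.box_edge <= 0:
            raise ValueError("box edge must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def box_nm(self) -> float:
        return self.box_edge * ANGSTROM_TO_NM

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def with_temperature(self, temperature: float) -> "SystemComposition":
        return SystemComposition(dict(self.counts), self.box_edge, temperature)


def wrap_positions(positions: np.ndarray, box: float) -> np.ndarray:
    """Wrap coordinates into the primary cell [0, box)."""
    wrapped = np.mod(positions, box)
    # np.mod of a tiny negative value can round to exactly `box`
    return np.where(wrapped >= box, wrapped - box, wrapped)


def minimum_image(delta: np.ndarray, box: float) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return delta - box * np.round(delta / box)


@dataclass
class Frame:
    """One snapshot: wrapped positions (nm) in a cubic periodic box."""

    positions: np.ndarray  # (N, 3) nm
    box: float  # nm
    step: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.box <= 0:
            raise ValueError("box edge must be > 0")


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology at one temperature."""

    topology: Topology
    frames: list[Frame]
    temperature: float = 298.15
    seed: int | None = None
    stride: int = 1

    def __post_init__(self) -> None:
        n = self.topology.n_sites
        for f in self.frames:
            if f.positions.shape[0] != n:
                raise ValueError("frame site count does not match topology")
        boxes = {round(f.box, 12) for f in self.frames}
        if len(boxes) > 1:
            raise ValueError("frames do not share a box edge")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def box(self) -> float:
        if not self.frames:
            raise ValueError("empty trajectory has no box")
        return self.frames[0].box

    def coordinates(self) -> np.ndarray:
        """(F, N, 3) stacked positions."""
        return np.stack([f.positions for f in self.frames])

    def subset(self, frame_indices: np.ndarray) -> "Trajectory":
        """A trajectory restricted to the given frame indices (e.g. a block)."""
        frames = [self.frames[int(i)] for i in np.asarray(frame_indices)]
        return Trajectory(self.topology, frames, self.temperature, self.seed, self.stride)


@dataclass
class LambdaState:
    """Samples of dV/dlambda collected in the ensemble at one lambda."""

    lam: float
    dvdl_samples: np.ndarray  # kJ/mol

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        self.dvdl_samples = np.asarray(self.dvdl_samples, dtype=float)
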