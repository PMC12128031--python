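"""Trajectory reading/writing (extended XYZ, GRO) and point selections.

Two plain-text dialects are supported:

* **extended XYZ** — per frame: a site count line, a comment line of
  ``key=value`` pairs (``box`` in nm and ``step`` are written; unknown keys
  are ignored on read), then ``label x y z`` lines in nm.
* **GRO** — fixed-width columns, coordinates in nm, one cubic box line per
  frame; velocities are ignored on read and omitted on write.

Coordinates are wrapped into the primary cell on ingest; downstream
distance math is minimum-image throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import (
    Frame,
    HydrosolvError,
    ParticleSpecies,
    Topology,
    Trajectory,
    minimum_image,
    wrap_positions,
)


class TrajectoryFormatError(HydrosolvError):
    """Malformed trajectory file."""


class SelectionError(HydrosolvError):
    """A selection cannot be resolved against the topology."""


# ---------------------------------------------------------------------------
# writing


def write_trajectory(trajectory: Trajectory, path: str | Path, format: str = "xyz-ext") -> None:
    """Write a trajectory; round-trips through :func:`read_trajectory` at
    format precision (1e-6 nm for xyz-ext, 1e-3 nm for gro)."""
    if trajectory.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    if format == "xyz-ext":
        text = _format_xyz(trajectory)
    elif format == "gro":
        text = _format_gro(trajectory)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    path.write_text(text)


def _format_xyz(traj: Trajectory) -> str:
    labels = traj.topology.labels
    out: list[str] = []
    for frame in traj.frames:
        out.append(str(len(labels)))
        out.append(f"box={frame.box:.6f} step={frame.step}")
        for lab, (x, y, z) in zip(labels, frame.positions):
            out.append(f"{lab} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(out) + "\n"


def _format_gro(traj: Trajectory) -> str:
    labels = traj.topology.labels
    mol = traj.topology.molecule_ids
    out: list[str] = []
    for frame in traj.frames:
        out.append(f"frame step={frame.step}")
        out.append(f"{len(labels):5d}")
        for i, (lab, (x, y, z)) in enumerate(zip(labels, frame.positions)):
            resid = (int(mol[i]) + 1) % 100000
            atomid = (i + 1) % 100000
            out.append(
                f"{resid:5d}{lab[:5]:<5s}{lab[:5]:>5s}{atomid:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        out.append(f"{frame.box:10.5f}{frame.box:10.5f}{frame.box:10.5f}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# reading


def read_trajectory(
    path: str | Path,
    format: str = "xyz-ext",
    topology: Topology | None = None,
) -> Trajectory:
    """Read a trajectory file.

    If a topology is given, site labels are validated against it (unknown
    labels are an error) and its species parameters/molecule grouping are
    attached; otherwise a minimal topology of single-site, parameter-free
    species is constructed from the labels (GRO residue numbers define the
    molecule grouping).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if format == "xyz-ext":
        frames, labels, mols = _parse_xyz(lines)
    elif format == "gro":
        frames, labels, mols = _parse_gro(lines)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    top = _resolve_topology(labels, mols, topology)
    return Trajectory(top, frames)


def _parse_xyz(lines: list[str]):
    frames: list[Frame] = []
    labels: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(f"expected site count at line {i + 1}") from exc
        if i + 2 + n > len(lines):
            raise TrajectoryFormatError("truncated xyz frame")
        meta = _parse_keyvalues(lines[i + 1])
        if "box" not in meta:
            raise TrajectoryFormatError(f"missing box record in comment at line {i + 2}")
        box = float(meta["box"])
        step = int(float(meta.get("step", len(frames))))
        frame_labels: list[str] = []
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(f"malformed body line {i + 3 + k}")
            frame_labels.append(parts[0])
            pos[k] = [float(v) for v in parts[1:4]]
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels:
            raise TrajectoryFormatError("site labels/order differ across frames")
        frames.append(Frame(wrap_positions(pos, box), box, step=step))
        i += 2 + n
    if labels is None:
        raise TrajectoryFormatError("no frames in file")
    _check_counts(frames)
    return frames, labels, None


def _parse_keyvalues(line: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for tok in line.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def _parse_gro(lines: list[str]):
    frames: list[Frame] = []
    labels: list[str] | None = None
    mols: list[int] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        meta = _parse_keyvalues(title)
        try:
            n = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise TrajectoryFormatError(f"expected atom count at line {i + 2}") from exc
        if i + 3 + n > len(lines):
            raise TrajectoryFormatError("truncated gro frame (missing box line)")
        frame_labels: list[str] = []
        frame_mols: list[int] = []
        pos = np.empty((n, 3))
        for k in range(n):
            line = lines[i + 2 + k]
            try:
                frame_mols.append(int(line[0:5]) - 1)
                frame_labels.append(line[10:15].strip())
                pos[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except (ValueError, IndexError) as exc:
                raise TrajectoryFormatError(f"malformed gro line {i + 3 + k}") from exc
        box_parts = lines[i + 2 + n].split()
        if len(box_parts) < 3:
            raise TrajectoryFormatError("missing box record")
        box = float(box_parts[0])
        step = int(float(meta.get("step", len(frames))))
        if labels is None:
            labels, mols = frame_labels, frame_mols
        elif frame_labels != labels:
            raise TrajectoryFormatError("site labels/order differ across frames")
        frames.append(Frame(wrap_positions(pos, box), box, step=step))
        i += 3 + n
    if labels is None:
        raise TrajectoryFormatError("no frames in file")
    _check_counts(frames)
    return frames, labels, mols


def _check_counts(frames: list[Frame]) -> None:
    counts = {f.positions.shape[0] for f in frames}
    if len(counts) > 1:
        raise TrajectoryFormatError("inconsistent site counts across frames")


def _resolve_topology(
    labels: list[str], mols: list[int] | None, topology: Topology | None
) -> Topology:
    if topology is not None:
        if topology.labels != labels:
            known = set(sp.name for sp in topology.species)
            unknown = sorted(set(labels) - known)
            if unknown:
                raise TrajectoryFormatError(f"unknown species labels {unknown}")
            raise TrajectoryFormatError("site order does not match topology")
        return topology
    table: dict[str, ParticleSpecies] = {}
    species = []
    for lab in labels:
        sp = table.setdefault(lab, ParticleSpecies(lab, 0.0, 0.0, 0.0, 1.0))
        species.append(sp)
    if mols is None:
        mol_ids = np.arange(len(labels), dtype=np.intp)
    else:
        # renumber file residue ids contiguously, preserving order
        seen: dict[int, int] = {}
        mol_ids = np.asarray([seen.setdefault(m, len(seen)) for m in mols], dtype=np.intp)
    return Topology(species, mol_ids)


# ---------------------------------------------------------------------------
# selections


@dataclass(frozen=True)
class SelectionSpec:
    """Which points of each frame a structure analysis should see.

    mode:
        ``"site"`` — every matching site individually;
        ``"molecule-COM"`` — the mass-weighted centre of each molecule that
        contains at least one matching site (periodic-unwrap before
        averaging);
        ``"central-site"`` — one designated site (by label) per matching
        molecule.
    species:
        Optional set of site labels to match (None = all).
    central_site:
        Required for ``central-site`` mode: the designated site label, of
        which each matching molecule must contain exactly one.
    """

    mode: str = "site"
    species: frozenset[str] | None = None
    central_site: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("site", "molecule-COM", "central-site"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "central-site" and self.central_site is None:
            raise ValueError("central-site mode requires a designated site label")
        if self.species is not None:
            object.__setattr__(self, "species", frozenset(self.species))


@dataclass
class ResolvedSelection:
    """Per-frame point sets plus the molecule id of each point."""

    points: np.ndarray  # (F, M, 3)
    molecule_ids: np.ndarray  # (M,)

    @property
    def n_points(self) -> int:
        return self.points.shape[1]


def resolve_selection(trajectory: Trajectory, selection: SelectionSpec) -> ResolvedSelection:
    """Resolve a :class:`SelectionSpec` to per-frame coordinates.

    Molecule centres of mass are computed with periodic unwrapping: each site
    is imaged nearest to the molecule's first site before mass-weighted
    averaging, and the centre is wrapped back into the box.  Molecules whose
    unwrapped extent exceeds half the box are rejected as ambiguous.
    """
    top = trajectory.topology
    box = trajectory.box
    labels = np.asarray(top.labels)
    want = (
        np.ones(top.n_sites, bool)
        if selection.species is None
        else np.isin(labels, sorted(selection.species))
    )
    coords = trajectory.coordinates()

    if selection.mode == "site":
        idx = np.flatnonzero(want)
        if idx.size == 0:
            raise SelectionError("selection matches no sites")
        return ResolvedSelection(coords[:, idx, :], top.molecule_ids[idx])

    mol_sites = top.molecule_sites()
    chosen_mols = [m for m, sites in enumerate(mol_sites) if np.any(want[sites])]
    if not chosen_mols:
        raise SelectionError("selection matches no molecules")

    if selection.mode == "central-site":
        idx = []
        for m in chosen_mols:
            sites = mol_sites[m]
            hits = sites[labels[sites] == selection.central_site]
            if hits.size != 1:
                raise SelectionError(
                    f"molecule {m} has {hits.size} sites labelled "
                    f"{selection.central_site!r}; central-site mode needs exactly one"
                )
            idx.append(int(hits[0]))
        idx = np.asarray(idx)
        return ResolvedSelection(coords[:, idx, :], top.molecule_ids[idx])

    # molecule-COM
    masses = top.array("mass")
    F = coords.shape[0]
    pts = np.empty((F, len(chosen_mols), 3))
    for j, m in enumerate(chosen_mols):
        sites = mol_sites[m]
        msub = masses[sites]
        ref = coords[:, sites[0], :][:, None, :]
        imaged = ref + minimum_image(coords[:, sites, :] - ref, box)
        extent = imaged.max(axis=1) - imaged.min(axis=1)
        if np.any(extent > box / 2):
            raise SelectionError(
                f"molecule {m} spans more than half the box; COM is ambiguous"
            )
        com = (imaged * msub[None, :, None]).sum(axis=1) / msub.sum()
        pts[:, j, :] = wrap_positions(com, box)
    return ResolvedSelection(pts, np.asarray(chosen_mols, dtype=np.intp))
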