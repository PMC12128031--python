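"""Structural order parameters for protein-like coordinate sets.

RMSD (with optimal rigid-body superposition), radius of gyration,
solvent-accessible surface area, geometric hydrogen-bond counts, and the
two-coordinate free-energy landscape F(x, y) = -kB T ln[P(x, y)/P_max]
built from joint histograms of two observables (conventionally Rg and SASA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB
from .model import HydrosolvError, minimum_image


class ProteinObsError(HydrosolvError):
    pass


@dataclass
class StructureFrame:
    """Labeled points with masses, radii and optional H-bond annotations.

    ``donors`` lists (donor heavy atom index, attached hydrogen index)
    pairs — exactly one hydrogen per listed donor; ``acceptors`` lists
    acceptor indices.  ``box`` (nm) enables minimum-image geometry; without
    it coordinates are treated as unwrapped.
    """

    positions: np.ndarray  # (N, 3) nm
    masses: np.ndarray | None = None  # amu
    radii: np.ndarray | None = None  # nm
    labels: list[str] | None = None
    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    box: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        n = self.positions.shape[0]
        if self.masses is None:
            self.masses = np.ones(n)
        self.masses = np.asarray(self.masses, float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be > 0")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, float)
            if np.any(self.radii < 0):
                raise ValueError("radii must be >= 0")
        seen = [d for d, _ in self.donors]
        if len(seen) != len(set(seen)):
            raise ValueError("each donor must list exactly one hydrogen")

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


def _delta(a: np.ndarray, b: np.ndarray, box: float | None) -> np.ndarray:
    d = a - b
    return minimum_image(d, box) if box else d


def kabsch_rmsd(
    reference: StructureFrame,
    frame: StructureFrame,
    weights: np.ndarray | None = None,
    superpose: bool = True,
) -> float:
    """Mass-weighted RMSD after optimal rigid superposition (nm).

    The minimising rotation is the weighted Kabsch solution; with
    ``superpose=False`` the raw (unfitted) deviation from the reference is
    returned instead, which conflates rigid-body motion with conformational
    change and is provided only for literal comparability.
    """
    a = np.asarray(reference.positions, float)
    b = np.asarray(frame.positions, float)
    if a.shape != b.shape:
        raise ProteinObsError("point counts differ between frames")
    w = reference.masses if weights is None else np.asarray(weights, float)
    if w.shape[0] != a.shape[0]:
        raise ProteinObsError("weight length mismatch")
    wsum = w.sum()
    if not superpose:
        return float(np.sqrt((w * ((a - b) ** 2).sum(axis=1)).sum() / wsum))
    ac = a - (w[:, None] * a).sum(axis=0) / wsum
    bc = b - (w[:, None] * b).sum(axis=0) / wsum
    if np.allclose(ac, 0) or np.allclose(bc, 0):
        return 0.0  # degenerate: all points coincident
    rot, rssd = Rotation.align_vectors(ac, bc, weights=w)
    # rssd = sqrt(sum_i w_i |a_i - R b_i|^2)
    return float(rssd / np.sqrt(wsum))


def radius_of_gyration(frame: StructureFrame) -> float:
    """sqrt( sum_i m_i |r_i - R_cm|^2 / M ), in nm."""
    if frame.n_points == 0:
        raise ProteinObsError("empty frame")
    m = frame.masses
    com = (m[:, None] * frame.positions).sum(axis=0) / m.sum()
    sq = ((frame.positions - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * sq).sum() / m.sum()))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    frame: StructureFrame,
    probe_radius: float = 0.14,
    n_sphere_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Solvent-accessible surface area by surface-point sampling (nm^2).

    For each point, test points on a deterministic Fibonacci lattice over
    the inflated sphere of radius r_i + probe; the accessible fraction (not
    buried inside any other inflated sphere) times the sphere area gives the
    per-point SASA.  Returns (total, per-point array).
    """
    if frame.radii is None:
        raise ProteinObsError("SASA requires per-point radii")
    if probe_radius < 0:
        raise ProteinObsError("probe radius must be >= 0")
    if n_sphere_points < 12:
        raise ProteinObsError("need at least 12 sphere points")
    pos = frame.positions
    R = frame.radii + probe_radius
    n = frame.n_points
    unit = _fibonacci_sphere(n_sphere_points)
    areas = np.zeros(n)
    for i in range(n):
        if R[i] == 0:
            continue
        pts = pos[i] + R[i] * unit
        # neighbours whose inflated spheres can bury points of sphere i
        d = _delta(pos, pos[i], frame.box)
        dist = np.sqrt((d * d).sum(axis=1))
        neigh = np.flatnonzero((dist < R + R[i]) & (np.arange(n) != i))
        buried = np.zeros(n_sphere_points, dtype=bool)
        for j in neigh:
            dj = _delta(pts, pos[j], frame.box)
            buried |= (dj * dj).sum(axis=1) < R[j] ** 2
        frac = 1.0 - buried.mean()
        areas[i] = frac * 4.0 * np.pi * R[i] ** 2
    return float(areas.sum()), areas


def hbond_count(
    frame: StructureFrame,
    partner: StructureFrame | None = None,
    distance_cutoff: float = 0.35,
    angle_cutoff: float = 30.0,
) -> int:
    """Count geometric hydrogen bonds between donors and acceptors.

    A donor-acceptor pair is bonded when the donor-heavy-atom to acceptor
    distance is <= ``distance_cutoff`` (nm) and the D-H...A arrangement
    deviates from linearity by <= ``angle_cutoff`` degrees (minimum image
    when a box is set).  Donors come from ``frame``; acceptors from
    ``partner`` (or from ``frame`` itself when no partner is given).
    The criterion is a conventional implementation choice and should be
    reported alongside any counts.
    """
    acc_frame = partner if partner is not None else frame
    if not frame.donors or not acc_frame.acceptors:
        return 0
    box = frame.box
    count = 0
    cos_limit = np.cos(np.radians(180.0 - angle_cutoff))
    for d_idx, h_idx in frame.donors:
        rd = frame.positions[d_idx]
        rh = frame.positions[h_idx]
        for a_idx in acc_frame.acceptors:
            ra = acc_frame.positions[a_idx]
            if partner is None and a_idx in (d_idx, h_idx):
                continue
            da = _delta(ra, rd, box)
            if (da * da).sum() > distance_cutoff**2:
                continue
            hd = _delta(rd, rh, box)
            ha = _delta(ra, rh, box)
            nh, na = np.linalg.norm(hd), np.linalg.norm(ha)
            if nh == 0 or na == 0:
                continue
            cos_dha = float(hd @ ha) / (nh * na)
            # linear D-H...A has angle 180 deg at H (cos = -1)
            if cos_dha <= cos_limit:
                count += 1
    return count


@dataclass
class FELGrid:
    """Two-coordinate free-energy landscape relative to its minimum."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # kJ/mol; nan on empty cells
    occupied: np.ndarray  # bool mask
    temperature: float
    probabilities: np.ndarray  # empirical cell probabilities
    flags: list[str] = field(default_factory=list)


def free_energy_landscape(
    series1: np.ndarray,
    series2: np.ndarray,
    temperature: float,
    n_bins: int = 50,
) -> FELGrid:
    """F(x, y) = -kB T ln[P(x, y)/P_max] from two equal-length series.

    The global minimum over occupied cells is 0 by construction; empty
    cells are masked.  Degenerate single-cell landscapes are valid and
    flagged.
    """
    x = np.asarray(series1, float)
    y = np.asarray(series2, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ProteinObsError("series must be equal-length 1-D arrays")
    if temperature <= 0:
        raise ProteinObsError("temperature must be > 0")
    if x.size == 0:
        raise ProteinObsError("empty series")

    def _edges(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        return np.linspace(lo, hi, n_bins + 1)

    counts, xe, ye = np.histogram2d(x, y, bins=[_edges(x), _edges(y)])
    p = counts / counts.sum()
    occupied = p > 0
    f = np.full_like(p, np.nan)
    f[occupied] = -KB * temperature * np.log(p[occupied] / p.max())
    flags = []
    if occupied.sum() == 1:
        flags.append("single-cell landscape")
    return FELGrid(xe, ye, f, occupied, temperature, p, flags)
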