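"""Pair structure analyses: g(r), coordination numbers, shell angles.

The pair radial distribution function g(r) is the density of target points
at distance r from a reference point relative to the ideal-gas expectation.
All distances are minimum-image; pairs of points belonging to the same
molecule are always excluded, so every g(r) here is intermolecular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .model import HydrosolvError, Trajectory, minimum_image
from .trajio import ResolvedSelection, SelectionSpec, resolve_selection


class StructureError(HydrosolvError):
    pass


@dataclass
class RDFResult:
    """A histogram-estimated pair radial distribution function.

    ``counts`` holds the raw accumulated pair tallies per bin (over all
    frames) so that pair-count bookkeeping can be audited downstream.
    """

    r: np.ndarray  # bin centres, nm
    g: np.ndarray  # dimensionless
    bin_width: float  # nm
    n_reference: int
    n_target: int
    rho_target: float  # nm^-3
    counts: np.ndarray  # raw pair counts per bin
    n_frames: int
    same_selection: bool = False

    @property
    def r_max(self) -> float:
        return float(self.r[-1] + self.bin_width / 2)


def _resolve(traj: Trajectory, sel) -> ResolvedSelection:
    if isinstance(sel, SelectionSpec):
        return resolve_selection(traj, sel)
    if isinstance(sel, ResolvedSelection):
        return sel
    raise TypeError("selection must be a SelectionSpec or ResolvedSelection")


def _selections_coincide(a: ResolvedSelection, b: ResolvedSelection) -> bool:
    return (
        a.n_points == b.n_points
        and np.array_equal(a.molecule_ids, b.molecule_ids)
        and np.array_equal(a.points, b.points)
    )


def rdf(
    trajectory: Trajectory,
    reference,
    target,
    bin_width: float = 0.01,
    r_max: float | None = None,
) -> RDFResult:
    """Histogram estimator of g(r) between two selections.

    Self-pairs and same-molecule pairs are excluded.  Counts are normalised
    by frames x reference count x ideal shell count
    rho_target * 4/3 pi [(r+dr)^3 - r^3]; if the two selections coincide each
    unordered pair is counted once and the normalisation halved.
    """
    ref = _resolve(trajectory, reference)
    tgt = _resolve(trajectory, target)
    box = trajectory.box
    if r_max is None:
        r_max = box / 2
    if r_max > box / 2 + 1e-12:
        raise StructureError(f"r_max={r_max} exceeds half the box edge {box / 2}")
    if ref.n_points == 0 or tgt.n_points == 0:
        raise StructureError("empty selection")

    same = _selections_coincide(ref, tgt)
    nbins = int(np.floor(r_max / bin_width + 1e-9))
    edges = bin_width * np.arange(nbins + 1)
    counts = np.zeros(nbins)
    exclude = ref.molecule_ids[:, None] == tgt.molecule_ids[None, :]
    for f in range(trajectory.n_frames):
        d = minimum_image(ref.points[f][:, None, :] - tgt.points[f][None, :, :], box)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        dist[exclude] = np.inf
        if same:
            dist[np.tril_indices(ref.n_points)] = np.inf
        counts += np.histogram(dist[np.isfinite(dist)], bins=edges)[0]

    volume = box**3
    rho = tgt.n_points / volume
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = trajectory.n_frames * ref.n_points * rho * shell
    if same:
        norm = norm / 2.0
    g = np.where(norm > 0, counts / norm, 0.0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(
        r=centres,
        g=g,
        bin_width=bin_width,
        n_reference=ref.n_points,
        n_target=tgt.n_points,
        rho_target=rho,
        counts=counts,
        n_frames=trajectory.n_frames,
        same_selection=same,
    )


def coordination_number(
    rdf_result: RDFResult, r_cut: float, method: str = "midpoint"
) -> float:
    """Running coordination number n(r_cut) = 4 pi rho ∫ g r^2 dr.

    ``method="midpoint"`` sums g(r) r^2 dr over bins with centre below
    r_cut (consistent with the histogram estimator); ``"trapezoid"`` uses
    trapezoidal quadrature on the bin centres.
    """
    if r_cut > rdf_result.r_max + 1e-12:
        raise StructureError(f"r_cut={r_cut} outside rdf grid (r_max={rdf_result.r_max})")
    sel = rdf_result.r < r_cut
    if not np.any(sel):
        return 0.0
    r, g = rdf_result.r[sel], rdf_result.g[sel]
    pref = 4.0 * np.pi * rdf_result.rho_target
    if method == "midpoint":
        return float(pref * np.sum(g * r**2) * rdf_result.bin_width)
    if method == "trapezoid":
        return float(pref * np.trapezoid(g * r**2, r))
    raise ValueError(f"unknown quadrature method {method!r}")


def smooth_moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge truncation (window in bins, odd)."""
    if window <= 1:
        return np.asarray(y, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def first_minimum(
    rdf_result: RDFResult,
    window: int = 5,
    prominence: float = 0.05,
) -> float | None:
    """First local minimum of (smoothed) g after its first prominent maximum.

    Returns None when no maximum of at least the given prominence exists
    (monotone or flat profiles); callers then fall back to a fixed cutoff,
    conventionally 1 nm for featureless solute-solute profiles.
    """
    if rdf_result.r.size < 5:
        raise StructureError("rdf has fewer than 5 bins")
    gs = smooth_moving_average(rdf_result.g, window)
    maxima, _ = find_peaks(gs, prominence=prominence)
    if maxima.size == 0:
        return None
    first_max = maxima[0]
    minima, _ = find_peaks(-gs)
    minima = minima[minima > first_max]
    if minima.size == 0:
        return None
    return float(rdf_result.r[minima[0]])


@dataclass
class ShellAngleDistribution:
    """Probability density of cos(theta) for probe orientations in a shell."""

    cos_theta: np.ndarray  # bin centres in [-1, 1]
    density: np.ndarray  # integrates to 1 over [-1, 1]
    shell: tuple[float, float]  # (r_min, r_max), nm
    n_observations: int


def shell_angle_distribution(
    trajectory: Trajectory,
    solute,
    probe,
    axes,
    shell: tuple[float, float],
    n_bins: int = 40,
) -> ShellAngleDistribution:
    """Orientation distribution of probe molecules in a solute's shell.

    For every probe point within ``shell = (r_min, r_max)`` of any solute
    point, accumulate cos(theta) between the probe's axis vector and the
    solute-to-probe displacement (minimum image, taken from the nearest
    solute point).

    ``axes`` defines each probe molecule's axis: either a pair of site
    labels ``(a, b)`` resolved within each probe molecule (vector from the
    ``a`` site to the ``b`` site, e.g. a dipole proxy), or an array of
    explicit vectors with shape (F, M, 3) matching the probe selection.
    """
    sol = _resolve(trajectory, solute)
    prb = _resolve(trajectory, probe)
    box = trajectory.box
    r_min, r_max = shell
    if r_min < 0 or r_max <= r_min:
        raise StructureError("invalid shell bounds")

    F, M = prb.points.shape[:2]
    if isinstance(axes, np.ndarray):
        axis_vec = np.asarray(axes, dtype=float)
        if axis_vec.shape != (F, M, 3):
            raise StructureError(f"axis array must have shape {(F, M, 3)}")
    else:
        axis_vec = _axes_from_site_labels(trajectory, prb, axes)

    cos_vals: list[np.ndarray] = []
    for f in range(F):
        d = minimum_image(prb.points[f][:, None, :] - sol.points[f][None, :, :], box)
        dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        nearest = np.argmin(dist, axis=1)
        r_near = dist[np.arange(M), nearest]
        in_shell = (r_near >= r_min) & (r_near < r_max)
        if not np.any(in_shell):
            continue
        # d rows are probe - solute, i.e. the solute -> probe displacement
        disp = d[np.arange(M), nearest][in_shell]
        ax = axis_vec[f][in_shell]
        nd = np.linalg.norm(disp, axis=1)
        na = np.linalg.norm(ax, axis=1)
        ok = (nd > 0) & (na > 0)
        cosq = np.einsum("ij,ij->i", disp[ok], ax[ok]) / (nd[ok] * na[ok])
        cos_vals.append(np.clip(cosq, -1.0, 1.0))

    samples = np.concatenate(cos_vals) if cos_vals else np.empty(0)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(samples, bins=edges)
    width = edges[1] - edges[0]
    total = hist.sum()
    density = hist / (total * width) if total > 0 else np.zeros(n_bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return ShellAngleDistribution(centres, density, (r_min, r_max), int(total))


def _axes_from_site_labels(
    trajectory: Trajectory, probe: ResolvedSelection, labels: tuple[str, str]
) -> np.ndarray:
    a_label, b_label = labels
    top = trajectory.topology
    coords = trajectory.coordinates()
    site_labels = np.asarray(top.labels)
    mol_sites = top.molecule_sites()
    a_idx, b_idx = [], []
    for m in probe.molecule_ids:
        sites = mol_sites[int(m)]
        a_hit = sites[site_labels[sites] == a_label]
        b_hit = sites[site_labels[sites] == b_label]
        if a_hit.size != 1 or b_hit.size != 1:
            raise StructureError(
                f"probe molecule {int(m)} lacks unique axis sites "
                f"({a_label!r}, {b_label!r})"
            )
        a_idx.append(int(a_hit[0]))
        b_idx.append(int(b_hit[0]))
    vec = minimum_image(
        coords[:, b_idx, :] - coords[:, a_idx, :], trajectory.box
    )
    return vec
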