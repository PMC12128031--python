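"""Distance-resolved preferential interaction coefficient Gamma(r).

Gamma measures the excess number of cosolvent molecules in the local domain
of a solute relative to the bulk cosolvent/water ratio:

    Gamma(r) = < n_c(r) - [n_c_tot - n_c(r)] / [n_w_tot - n_w(r)] * n_w(r) >

where n_c(r) and n_w(r) count cosolvent and water molecules within distance
r of the solute surface (here: of the nearest solute selection point), and
the angle brackets average over frames.  Positive Gamma means accumulation
(denaturant-like), negative means exclusion (protectant-like).  The cutoff
r* separating the local from the bulk domain is chosen where the Gamma(r)
profile flattens out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import HydrosolvError, Trajectory, minimum_image
from .structure import _resolve


class PreferentialError(HydrosolvError):
    pass


@dataclass
class GammaProfile:
    """Gamma on an r grid, with per-r counts of excluded (undefined) frames."""

    r: np.ndarray  # nm
    gamma: np.ndarray
    n_cosolvent_total: int
    n_water_total: int
    n_frames: int
    excluded_frames: np.ndarray  # per-r count of frames with zero denominator
    cutoff: float | None = None
    gamma_at_cutoff: float | None = None
    gamma_sd: float | None = None
    per_frame: np.ndarray | None = None  # (F, R); nan where undefined


def _nearest_solute_distances(
    solute_pts: np.ndarray, probe_pts: np.ndarray, box: float
) -> np.ndarray:
    d = minimum_image(probe_pts[:, None, :] - solute_pts[None, :, :], box)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    return dist.min(axis=1)


def _per_frame_gamma(
    trajectory: Trajectory, solute, cosolvent, water, r_grid: np.ndarray
) -> tuple[np.ndarray, int, int]:
    sol = _resolve(trajectory, solute)
    cos = _resolve(trajectory, cosolvent)
    wat = _resolve(trajectory, water)
    for a, b, names in (
        (sol, cos, "solute/cosolvent"),
        (sol, wat, "solute/water"),
        (cos, wat, "cosolvent/water"),
    ):
        if np.intersect1d(a.molecule_ids, b.molecule_ids).size:
            raise PreferentialError(f"{names} selections share molecules")
    if wat.n_points == 0:
        raise PreferentialError("empty water selection")
    box = trajectory.box
    r_grid = np.asarray(r_grid, float)
    if np.any(r_grid > box / 2 + 1e-12):
        raise PreferentialError("r grid exceeds half the box edge")

    nc_tot, nw_tot = cos.n_points, wat.n_points
    F = trajectory.n_frames
    values = np.full((F, r_grid.size), np.nan)
    for f in range(F):
        dc = np.sort(_nearest_solute_distances(sol.points[f], cos.points[f], box))
        dw = np.sort(_nearest_solute_distances(sol.points[f], wat.points[f], box))
        n_c = np.searchsorted(dc, r_grid, side="right").astype(float)
        n_w = np.searchsorted(dw, r_grid, side="right").astype(float)
        denom = nw_tot - n_w
        ok = denom > 0
        values[f, ok] = n_c[ok] - (nc_tot - n_c[ok]) / denom[ok] * n_w[ok]
    return values, nc_tot, nw_tot


def gamma_profile(
    trajectory: Trajectory,
    solute,
    cosolvent,
    water,
    r_grid: np.ndarray,
) -> GammaProfile:
    """Frame-averaged Gamma(r) over a distance grid.

    The bracket is evaluated per frame and then averaged; frames where the
    bulk-water denominator vanishes at a given r are excluded from that r's
    average and tallied in ``excluded_frames``.
    """
    r_grid = np.asarray(r_grid, float)
    values, nc_tot, nw_tot = _per_frame_gamma(
        trajectory, solute, cosolvent, water, r_grid
    )
    excluded = np.isnan(values).sum(axis=0)
    with np.errstate(invalid="ignore"):
        gamma = np.nanmean(values, axis=0)
    return GammaProfile(
        r=r_grid,
        gamma=gamma,
        n_cosolvent_total=nc_tot,
        n_water_total=nw_tot,
        n_frames=trajectory.n_frames,
        excluded_frames=excluded,
        per_frame=values,
    )


def select_cutoff(
    profile: GammaProfile, window: float = 0.2, tolerance: float = 0.1
) -> float | None:
    """Smallest r at which Gamma has plateaued.

    Returns the first grid point r such that the range (max - min) of Gamma
    over the trailing window of width ``window`` nm, fully inside the grid,
    is below ``tolerance``.  None (no-plateau diagnostic) if the profile
    never flattens; callers may then force a cutoff.
    """
    r, g = profile.r, profile.gamma
    for i in range(r.size):
        lo = r[i] - window
        if lo < r[0] - 1e-12:
            continue
        sel = (r > lo - 1e-12) & (r <= r[i] + 1e-12)
        vals = g[sel]
        if np.any(np.isnan(vals)):
            continue
        if vals.max() - vals.min() < tolerance:
            return float(r[i])
    return None


@dataclass
class GammaEstimate:
    """Point estimate of Gamma at a fixed cutoff with block-analysis sd."""

    cutoff: float
    value: float
    sd: float
    n_blocks: int
    excluded_frames: int
    flags: list[str] = field(default_factory=list)


def gamma_estimate(
    trajectory: Trajectory,
    solute,
    cosolvent,
    water,
    cutoff: float,
    n_blocks: int = 5,
) -> GammaEstimate:
    """Gamma at a fixed cutoff, averaged over frames, with five-block sd.

    The uncertainty is the sample standard deviation across contiguous
    frame blocks (the same convention used for PMF block errors; the
    choice of error model is recorded in the flags).
    """
    values, _, _ = _per_frame_gamma(
        trajectory, solute, cosolvent, water, np.asarray([cutoff])
    )
    series = values[:, 0]
    defined = np.isfinite(series)
    flags = ["errors: contiguous block analysis"]
    excluded = int((~defined).sum())
    if not np.any(defined):
        return GammaEstimate(
            cutoff, float("nan"), float("nan"), n_blocks, excluded,
            flags + ["undefined: bulk-water denominator zero in every frame"],
        )
    value = float(series[defined].mean())
    blocks = np.array_split(series, n_blocks)
    block_means = np.asarray(
        [b[np.isfinite(b)].mean() if np.any(np.isfinite(b)) else np.nan for b in blocks]
    )
    good = np.isfinite(block_means)
    if good.sum() >= 2:
        sd = float(np.std(block_means[good], ddof=1))
    else:
        sd = float("nan")
        flags.append("undefined sd: fewer than two defined blocks")
    return GammaEstimate(cutoff, value, sd, n_blocks, excluded, flags)
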