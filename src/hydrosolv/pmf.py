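"""Potentials of mean force and their enthalpy/entropy decomposition.

The PMF along a solute-solute separation is W(r) = -kB T ln g(r), defined
only where g > 0.  Runs at three temperatures (T - dT, T, T + dT) give the
entropy by the finite-difference (central) derivative

    dS(r) = -[W(r, T+dT) - W(r, T-dT)] / (2 dT)

and the enthalpy by dH(r) = W(r, T) + T dS(r), under the assumption that the
heat capacity is constant over the temperature window.  Characteristic
extrema of a hydrophobic-association PMF — contact minimum (CM),
desolvation peak (DSP), solvent-separated minimum (SSM) — and their
differences (dG_u = DSP - CM, dG_f = SSM - DSP, dG_f2u = SSM - CM) are
extracted with the same smoothing conventions used for g(r) extrema.
Uncertainties come from contiguous block analysis (default five blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import find_peaks

from .constants import KB
from .model import HydrosolvError, Trajectory
from .structure import RDFResult, smooth_moving_average


class PMFError(HydrosolvError):
    pass


class FeatureExtractionError(PMFError):
    """The PMF has no usable minimum."""


@dataclass
class PMFProfile:
    """W(r) on an r grid with a validity mask (bins where g > 0)."""

    r: np.ndarray  # nm
    w: np.ndarray  # kJ/mol; undefined entries are nan
    temperature: float  # K
    valid: np.ndarray  # bool mask

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float)
        self.w = np.asarray(self.w, float)
        self.valid = np.asarray(self.valid, bool)
        if not (self.r.shape == self.w.shape == self.valid.shape):
            raise ValueError("r, w and valid must share a shape")


@dataclass
class ThermoDecomposition:
    """dG, dS, dH profiles from the three-temperature finite difference.

    dH - T dS = dG holds identically at every valid grid point; the
    constant-heat-capacity assumption of the scheme is recorded in
    ``assumes_constant_cv`` metadata rather than enforced.
    """

    r: np.ndarray
    dg: np.ndarray  # kJ/mol at T
    ds: np.ndarray  # kJ/(mol K)
    dh: np.ndarray  # kJ/mol
    temperature: float
    delta_t: float
    temperatures: tuple[float, float, float]
    valid: np.ndarray
    assumes_constant_cv: bool = True


@dataclass
class PMFFeatures:
    """CM/DSP/SSM extrema of a PMF and their free-energy differences.

    Each extremum is a (position nm, value kJ/mol) pair or None when absent;
    differences involving absent extrema are None and flagged.
    """

    cm: tuple[float, float] | None
    dsp: tuple[float, float] | None
    ssm: tuple[float, float] | None
    dg_u: float | None = None  # DSP - CM
    dg_f: float | None = None  # SSM - DSP
    dg_f2u: float | None = None  # SSM - CM
    flags: list[str] = field(default_factory=list)

    @classmethod
    def from_extrema(
        cls,
        cm: tuple[float, float] | None,
        dsp: tuple[float, float] | None,
        ssm: tuple[float, float] | None,
        flags: list[str] | None = None,
    ) -> "PMFFeatures":
        flags = list(flags or [])
        dg_u = dsp[1] - cm[1] if (dsp and cm) else None
        dg_f = ssm[1] - dsp[1] if (ssm and dsp) else None
        dg_f2u = ssm[1] - cm[1] if (ssm and cm) else None
        if dsp is None or ssm is None:
            flags.append("low-confidence: incomplete CM/DSP/SSM triplet")
        return cls(cm, dsp, ssm, dg_u, dg_f, dg_f2u, flags)


def pmf_from_rdf(rdf_result: RDFResult, temperature: float) -> PMFProfile:
    """W(r) = -kB T ln g(r); masked (nan) where g = 0."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    g = np.asarray(rdf_result.g, float)
    valid = g > 0
    w = np.full_like(g, np.nan)
    w[valid] = -KB * temperature * np.log(g[valid])
    return PMFProfile(rdf_result.r.copy(), w, temperature, valid)


def _check_grids(*profiles: PMFProfile) -> None:
    r0 = profiles[0].r
    for p in profiles[1:]:
        if p.r.shape != r0.shape or not np.allclose(p.r, r0):
            raise PMFError("PMF profiles are not on a shared r grid")


def entropy_finite_difference(
    w_minus: PMFProfile, w_plus: PMFProfile
) -> tuple[np.ndarray, np.ndarray, float]:
    """Central-difference entropy profile from runs at T-dT and T+dT.

    Returns (dS, valid mask, dT).  Exact for free energies linear in T.
    """
    _check_grids(w_minus, w_plus)
    dt2 = w_plus.temperature - w_minus.temperature
    if dt2 <= 0:
        raise PMFError("w_plus must be at the higher temperature")
    valid = w_minus.valid & w_plus.valid
    ds = np.full_like(w_minus.w, np.nan)
    ds[valid] = -(w_plus.w[valid] - w_minus.w[valid]) / dt2
    return ds, valid, dt2 / 2.0


def enthalpy(
    w_at_t: PMFProfile, ds: np.ndarray, temperature: float | None = None
) -> np.ndarray:
    """dH(r) = dG(r) + T dS(r), pointwise on the shared grid."""
    t = w_at_t.temperature if temperature is None else temperature
    ds = np.asarray(ds, float)
    if ds.shape != w_at_t.w.shape:
        raise PMFError("dS grid does not match the PMF grid")
    return w_at_t.w + t * ds


def decompose(
    w_minus: PMFProfile, w_mid: PMFProfile, w_plus: PMFProfile
) -> ThermoDecomposition:
    """Three-temperature finite-difference decomposition of a PMF."""
    _check_grids(w_minus, w_mid, w_plus)
    if not (w_minus.temperature < w_mid.temperature < w_plus.temperature):
        raise PMFError("temperatures must be strictly increasing")
    ds, valid_pm, dt = entropy_finite_difference(w_minus, w_plus)
    valid = valid_pm & w_mid.valid
    dh = enthalpy(w_mid, ds)
    dg = w_mid.w.copy()
    for arr in (ds, dh, dg):
        arr[~valid] = np.nan
    return ThermoDecomposition(
        r=w_mid.r.copy(),
        dg=dg,
        ds=ds,
        dh=dh,
        temperature=w_mid.temperature,
        delta_t=dt,
        temperatures=(w_minus.temperature, w_mid.temperature, w_plus.temperature),
        valid=valid,
    )


def _largest_valid_region(profile: PMFProfile) -> np.ndarray:
    """Indices of the largest contiguous valid region containing the global
    minimum of W."""
    valid = profile.valid & np.isfinite(profile.w)
    if not np.any(valid):
        raise FeatureExtractionError("PMF has no valid bins")
    idx = np.flatnonzero(valid)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    regions = np.split(idx, splits)
    gmin = idx[np.nanargmin(profile.w[idx])]
    for region in regions:
        if region[0] <= gmin <= region[-1]:
            return region
    return max(regions, key=len)


def extract_features(
    pmf: PMFProfile, window: int = 5, prominence: float = 0.05
) -> PMFFeatures:
    """Locate CM, DSP and SSM on a (smoothed) PMF and their differences.

    CM is the first local minimum of the smoothed W inside the largest
    contiguous valid region containing the global minimum; DSP the first
    local maximum of at least ``prominence`` after CM; SSM the first local
    minimum after DSP.  Values are read from the unsmoothed profile at the
    located bins.  Missing DSP/SSM yield None differences with a
    low-confidence flag (the near-asymptotic PMF case).
    """
    region = _largest_valid_region(pmf)
    w = pmf.w[region]
    r = pmf.r[region]
    ws = smooth_moving_average(w, window)

    minima, _ = find_peaks(-ws, prominence=prominence)
    if minima.size == 0:
        # permit an endpoint minimum only if it is the global one
        raise FeatureExtractionError("no local minimum found in the PMF")
    cm_i = int(minima[0])
    cm = (float(r[cm_i]), float(w[cm_i]))

    maxima, _ = find_peaks(ws, prominence=prominence)
    maxima = maxima[maxima > cm_i]
    flags: list[str] = []
    if maxima.size == 0:
        return PMFFeatures.from_extrema(cm, None, None, flags)
    dsp_i = int(maxima[0])
    dsp = (float(r[dsp_i]), float(w[dsp_i]))

    later_minima = minima[minima > dsp_i]
    if later_minima.size == 0:
        return PMFFeatures.from_extrema(cm, dsp, None, flags)
    ssm_i = int(later_minima[0])
    ssm = (float(r[ssm_i]), float(w[ssm_i]))
    return PMFFeatures.from_extrema(cm, dsp, ssm, flags)


@dataclass
class BlockErrorProfile:
    """Per-grid-point sample standard deviation across contiguous blocks."""

    sd: np.ndarray
    n_blocks: int
    block_values: np.ndarray  # (n_blocks, grid)


def block_errors(
    trajectory: Trajectory,
    estimator: Callable[[Trajectory], np.ndarray],
    n_blocks: int = 5,
) -> BlockErrorProfile:
    """Evaluate an estimator on contiguous near-equal frame blocks.

    ``estimator`` maps a trajectory to a 1-D array on a fixed grid (for
    example rdf -> pmf -> decomposition); the sample standard deviation
    (ddof=1) across the block estimates is returned per grid point.
    """
    if trajectory.n_frames < n_blocks:
        raise PMFError(
            f"need at least {n_blocks} frames for {n_blocks}-block analysis"
        )
    pieces = np.array_split(np.arange(trajectory.n_frames), n_blocks)
    values = []
    for b, piece in enumerate(pieces):
        try:
            values.append(np.asarray(estimator(trajectory.subset(piece)), float))
        except Exception as exc:
            raise PMFError(f"estimator failed in block {b}: {exc}") from exc
    block_values = np.stack(values)
    if n_blocks < 2:
        sd = np.zeros(block_values.shape[1])
    else:
        sd = np.std(block_values, axis=0, ddof=1)
    return BlockErrorProfile(sd=sd, n_blocks=n_blocks, block_values=block_values)
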