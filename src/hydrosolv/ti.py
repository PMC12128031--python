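"""Solvation free energies by thermodynamic integration over lambda.

A coupling parameter lambda switches a tagged solute's interactions off
linearly: V(lambda) = (1-lambda) V0 + lambda V1, with lambda = 0 fully
interacting and lambda = 1 ideal.  The switching work is the trapezoidal
integral of the per-lambda mean of dV/dlambda; since the path runs from the
solvated to the decoupled state, the solvation free energy of the solute is
the *negative* of that integral,

    dG_s = -∫_0^1 <dV/dlambda>_lambda dlambda,

so that dG_s < 0 means solvation is favourable and the value is directly
comparable with the Widom-insertion excess chemical potential
-kB T ln<exp(-dU/kB T)>.  Per-lambda uncertainties are five-block standard
errors, and quadrature weights propagate them to dG_s in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_K, KB
from .model import HydrosolvError, LambdaState, ParticleSpecies, Trajectory, minimum_image
from .simulator import DEFAULT_CUTOFF


class TIError(HydrosolvError):
    pass


@dataclass
class TIResult:
    """Thermodynamic-integration output for one solute/solvent/temperature."""

    lambdas: np.ndarray
    dvdl_mean: np.ndarray  # kJ/mol
    dvdl_se: np.ndarray  # kJ/mol, per-lambda block standard error
    switching_integral: float  # ∫ <dV/dl> dl, kJ/mol
    dg_s: float  # solvation free energy, kJ/mol
    dg_s_err: float  # kJ/mol
    temperature: float
    solvent: str = ""


@dataclass
class TransferResult:
    """Transfer free energy of a solute between two solvents."""

    solvent_from: str
    solvent_to: str
    ddg: float  # kJ/mol, dG_s(to) - dG_s(from)
    ddg_err: float


def _block_standard_error(samples: np.ndarray, n_blocks: int = 5) -> float:
    samples = np.asarray(samples, float)
    if samples.size < n_blocks:
        n_blocks = max(2, samples.size)
    if samples.size < 2:
        return 0.0
    means = np.asarray([b.mean() for b in np.array_split(samples, n_blocks)])
    return float(np.std(means, ddof=1) / np.sqrt(len(means)))


def integrate_ti(
    lambda_states: list[LambdaState],
    temperature: float,
    n_blocks: int = 5,
    solvent: str = "",
) -> TIResult:
    """Trapezoidal quadrature of <dV/dlambda> over a sorted [0, 1] grid.

    Requires both endpoints; empty sample sets at any lambda are an error.
    The error combines per-lambda block standard errors with the trapezoid
    weights in quadrature.
    """
    if len(lambda_states) < 2:
        raise TIError("need at least two lambda points")
    lams = np.asarray([s.lam for s in lambda_states], float)
    if np.any(np.diff(lams) <= 0):
        raise TIError("lambda grid must be strictly increasing")
    if abs(lams[0]) > 1e-12 or abs(lams[-1] - 1.0) > 1e-12:
        raise TIError("lambda grid must include both endpoints 0 and 1")
    for s in lambda_states:
        if s.dvdl_samples.size == 0:
            raise TIError(f"no dV/dlambda samples at lambda={s.lam}")
    means = np.asarray([s.dvdl_samples.mean() for s in lambda_states])
    ses = np.asarray(
        [_block_standard_error(s.dvdl_samples, n_blocks) for s in lambda_states]
    )
    # trapezoid weights: w_0 = dl_0/2, w_i = (dl_{i-1}+dl_i)/2, w_n = dl_{n-1}/2
    dl = np.diff(lams)
    w = np.zeros_like(lams)
    w[:-1] += dl / 2
    w[1:] += dl / 2
    integral = float(np.sum(w * means))
    err = float(np.sqrt(np.sum((w * ses) ** 2)))
    return TIResult(
        lambdas=lams,
        dvdl_mean=means,
        dvdl_se=ses,
        switching_integral=integral,
        dg_s=-integral,
        dg_s_err=err,
        temperature=temperature,
        solvent=solvent,
    )


def transfer_free_energy(ti_s1: TIResult, ti_s2: TIResult) -> TransferResult:
    """ddG(s1 -> s2) = dG_s(s2) - dG_s(s1), errors in quadrature."""
    if abs(ti_s1.temperature - ti_s2.temperature) > 1e-9:
        raise TIError("transfer free energy requires matching temperatures")
    return TransferResult(
        solvent_from=ti_s1.solvent,
        solvent_to=ti_s2.solvent,
        ddg=ti_s2.dg_s - ti_s1.dg_s,
        ddg_err=float(np.hypot(ti_s1.dg_s_err, ti_s2.dg_s_err)),
    )


def solvation_decomposition(
    ti_minus: TIResult, ti_plus: TIResult, ti_mid: TIResult
) -> tuple[float, float]:
    """(dS_s, dH_s) from TI runs at T-dT, T+dT and T.

    dS_s is the central temperature difference of dG_s (exact for dG_s linear
    in T); dH_s = dG_s(T) + T dS_s.
    """
    for a, b in ((ti_minus, ti_mid), (ti_mid, ti_plus)):
        if a.lambdas.shape != b.lambdas.shape or not np.allclose(a.lambdas, b.lambdas):
            raise TIError("TI results are not on a shared lambda grid")
    if not (ti_minus.temperature < ti_mid.temperature < ti_plus.temperature):
        raise TIError("temperatures must be strictly increasing")
    dt2 = ti_plus.temperature - ti_minus.temperature
    ds = -(ti_plus.dg_s - ti_minus.dg_s) / dt2
    dh = ti_mid.dg_s + ti_mid.temperature * ds
    return ds, dh


def widom_insertion(
    bath: Trajectory,
    solute: ParticleSpecies,
    n_insertions: int = 1000,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
    n_blocks: int = 5,
) -> tuple[float, float]:
    """Widom test-particle excess chemical potential of a solute in a bath.

    Inserts the solute at uniform random positions in every frame of a bath
    trajectory and returns (-kB T ln<exp(-dU/kB T)>, block standard error),
    with dU evaluated with the same truncated-and-shifted LJ (+ truncated
    Coulomb) convention the Monte-Carlo engine samples with.
    """
    rng = np.random.default_rng(seed)
    box = bath.box
    beta = 1.0 / (KB * bath.temperature)
    cutoff = min(cutoff, box / 2)
    sig = bath.topology.array("sigma")
    eps = bath.topology.array("epsilon")
    q = bath.topology.array("charge")
    sij = 0.5 * (solute.sigma + sig)
    eij = np.sqrt(solute.epsilon * eps)
    qq = solute.charge * q
    sc6 = np.where(sij > 0, (sij / cutoff) ** 6, 0.0)
    shift = 4.0 * eij * (sc6 * sc6 - sc6)

    frame_means = np.empty(bath.n_frames)
    for f, frame in enumerate(bath.frames):
        pts = rng.uniform(0.0, box, size=(n_insertions, 3))
        d = minimum_image(pts[:, None, :] - frame.positions[None, :, :], box)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        within = r2 <= cutoff**2
        r2 = np.maximum(r2, 1e-24)
        s6 = np.where(sij[None, :] > 0, (sij[None, :] ** 2 / r2) ** 3, 0.0)
        u = 4.0 * eij[None, :] * (s6 * s6 - s6) - shift[None, :]
        nz = qq != 0.0
        if np.any(nz):
            u[:, nz] += qq[None, nz] * COULOMB_K / np.sqrt(r2[:, nz])
        du = np.where(within, u, 0.0).sum(axis=1)
        frame_means[f] = np.exp(-beta * np.clip(du, -700 / beta, 700 / beta)).mean()
    mean_b = frame_means.mean()
    mu = -KB * bath.temperature * np.log(mean_b)
    blocks = np.array_split(frame_means, min(n_blocks, bath.n_frames))
    bm = np.asarray([b.mean() for b in blocks])
    se_b = np.std(bm, ddof=1) / np.sqrt(len(bm)) if len(bm) > 1 else 0.0
    mu_err = KB * bath.temperature * se_b / mean_b  # delta ln x = dx/x
    return float(mu), float(mu_err)
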