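"""Run configuration, composition utilities and the end-to-end pipeline.

The pipeline emulates the paper-shaped workflow on the built-in toy
simulator: NVT sampling at three temperatures (T - dT, T, T + dT), solute-
solute g(r), PMFs, the finite-difference enthalpy/entropy decomposition with
five-block errors, CM/DSP/SSM feature tables, and — when a cosolvent is
present — the distance-resolved preferential interaction coefficient with a
plateau-selected cutoff.  Every artifact carries the config hash and seed so
a run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import AVOGADRO, KB
from .model import HydrosolvError, ParticleSpecies, SystemComposition, Topology
from .pmf import (
    FeatureExtractionError,
    PMFFeatures,
    block_errors,
    decompose,
    extract_features,
    pmf_from_rdf,
)
from .preferential import gamma_estimate, gamma_profile, select_cutoff
from .simulator import run_nvt
from .structure import rdf
from .trajio import SelectionSpec, write_trajectory


class ConfigError(HydrosolvError):
    pass


class PipelineStageError(HydrosolvError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def molarity(count: int, box_edge_angstrom: float) -> float:
    """Molar concentration of ``count`` molecules in a cubic box (edge in Å)."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if box_edge_angstrom <= 0:
        raise ValueError("box edge must be > 0")
    volume_litres = box_edge_angstrom**3 * 1e-27  # 1 L = 1e27 A^3
    return count / (AVOGADRO * volume_litres)


# ---------------------------------------------------------------------------
# Reference composition and parameter tables (printed inputs).  Counts are
# molecules; box edges in Å; cosolvent molarities follow from molarity().

_HYDROCARBON_SOLVENT_ROWS = {
    "water": dict(n_solute=10, n_urea=0, n_tmao=0, n_water=3990, box_edge=49.6),
    "water-urea": dict(n_solute=10, n_urea=800, n_tmao=0, n_water=3190, box_edge=54.6),
    "water-TMAO": dict(n_solute=10, n_urea=0, n_tmao=323, n_water=3667, box_edge=53.6),
    "water-urea-TMAO": dict(
        n_solute=10, n_urea=801, n_tmao=320, n_water=2869, box_edge=57.0
    ),
}

REFERENCE_COMPOSITIONS: dict[str, dict[str, dict[str, float]]] = {
    solute: {k: dict(v) for k, v in _HYDROCARBON_SOLVENT_ROWS.items()}
    for solute in ("neopentane", "cyclohexane", "n-hexane")
}
REFERENCE_COMPOSITIONS["b2m"] = {
    "water": dict(n_solute=1, n_urea=0, n_tmao=0, n_water=16340, box_edge=80.0),
    "water-urea": dict(n_solute=1, n_urea=2517, n_tmao=0, n_water=8547, box_edge=80.0),
    "water-TMAO": dict(n_solute=1, n_urea=0, n_tmao=1073, n_water=11038, box_edge=80.0),
    "water-urea-TMAO": dict(
        n_solute=1, n_urea=2215, n_tmao=885, n_water=5855, box_edge=80.0
    ),
}

#: Site LJ parameters and charges of the modelled species (sigma nm,
#: epsilon kJ/mol, charge e): united-atom hydrocarbons, water, urea, TMAO.
REFERENCE_LJ_PARAMETERS: dict[str, dict[str, tuple[float, float, float]]] = {
    "neopentane": {"C_central": (0.3800, 0.2092, 0.0), "C_CH3": (0.3960, 0.6067, 0.0)},
    "cyclohexane": {"C": (0.3905, 0.4937, 0.0)},
    "n-hexane": {"C_CH3": (0.3905, 0.7322, 0.0), "C_CH2": (0.3905, 0.4937, 0.0)},
    "water": {"O": (0.3151, 0.6364, -0.8340), "H": (0.0, 0.0, 0.4170)},
    "urea": {
        "C": (0.3770, 0.4170, 0.9210),
        "N": (0.3110, 0.5000, -0.6930),
        "O": (0.3100, 0.5600, -0.6750),
        "H": (0.1580, 0.0880, 0.2850),
    },
    "TMAO": {
        "C": (0.3041, 0.2826, -0.260),
        "N": (0.2926, 0.8360, 0.440),
        "O": (0.3266, 0.6379, -0.650),
        "H": (0.1775, 0.0773, 0.110),
    },
}


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end pipeline run."""

    name: str
    species: list[dict]
    counts: dict[str, int]
    box_edge: float  # Å
    temperature: float = 298.15
    delta_t: float = 25.0
    seed: int = 0
    n_sweeps: int = 600
    stride: int = 10
    step_size: float = 0.08
    cutoff: float = 1.2
    rdf_bin_width: float = 0.02
    rdf_r_max: float | None = None
    solute_species: list[str] = field(default_factory=list)
    cosolvent_species: list[str] = field(default_factory=list)
    water_species: list[str] = field(default_factory=list)
    feature_window: int = 5
    feature_prominence: float = 0.05
    gamma_dr: float = 0.05
    gamma_window: float = 0.3
    gamma_tolerance: float = 0.25
    gamma_fallback_cutoff: float = 1.0
    n_blocks: int = 5

    def __post_init__(self) -> None:
        names = {s["name"] for s in self.species}
        for group, label in (
            (self.counts, "counts"),
            (self.solute_species, "solute_species"),
            (self.cosolvent_species, "cosolvent_species"),
            (self.water_species, "water_species"),
        ):
            for n in group:
                if n not in names:
                    raise ConfigError(f"{label} references undefined species {n!r}")
        if self.delta_t <= 0:
            raise ConfigError("delta_t must be > 0 (temperatures must increase)")
        if not self.solute_species:
            raise ConfigError("at least one solute species is required")

    @property
    def temperatures(self) -> tuple[float, float, float]:
        return (
            self.temperature - self.delta_t,
            self.temperature,
            self.temperature + self.delta_t,
        )

    def species_objects(self) -> dict[str, ParticleSpecies]:
        out = {}
        for s in self.species:
            out[s["name"]] = ParticleSpecies(
                s["name"],
                float(s["sigma"]),
                float(s["epsilon"]),
                float(s.get("charge", 0.0)),
                float(s.get("mass", 1.0)),
            )
        return out

    def topology(self) -> Topology:
        table = self.species_objects()
        return Topology.from_counts(
            {table[name]: n for name, n in self.counts.items() if n > 0}
        )

    def composition(self, temperature: float | None = None) -> SystemComposition:
        return SystemComposition(
            {k: v for k, v in self.counts.items() if v > 0},
            self.box_edge,
            self.temperature if temperature is None else temperature,
        )

    def canonical_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, sort_keys=True))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(data)


def demo_config(seed: int = 7, n_sweeps: int = 600) -> RunConfig:
    """A reduced ternary-mixture demo: 10 LJ solutes + ~400 bath particles.

    The species echo the united-atom solute and single-site water/cosolvent
    parameters of the modelled systems (charges off by default in the toy),
    at a reduced density so the whole pipeline runs in minutes.
    """
    return RunConfig(
        name="demo-ternary",
        species=[
            dict(name="S", sigma=0.3905, epsilon=0.4937, charge=0.0, mass=84.0),
            dict(name="W", sigma=0.3151, epsilon=0.6364, charge=0.0, mass=18.0),
            dict(name="C", sigma=0.3770, epsilon=0.4170, charge=0.0, mass=60.0),
        ],
        counts={"S": 10, "W": 330, "C": 70},
        box_edge=40.0,
        rdf_bin_width=0.03,  # toy-scale statistics need coarser bins
        temperature=298.15,
        delta_t=25.0,
        seed=seed,
        n_sweeps=n_sweeps,
        stride=10,
        solute_species=["S"],
        cosolvent_species=["C"],
        water_species=["W"],
    )


# ---------------------------------------------------------------------------
# pipeline


def _fmt(x) -> object:
    if isinstance(x, (np.floating, float)):
        return None if not np.isfinite(x) else round(float(x), 10)
    return x


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full simulate -> g(r) -> PMF -> decomposition -> features ->
    Gamma workflow and write all artifacts plus a deterministic manifest.

    Returns the manifest dict.  Any stage failure raises
    :class:`PipelineStageError`; artifacts written before the failure are
    preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.canonical_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "temperatures": list(config.temperatures),
        "outputs": {},
        "stages": [],
    }
    top = config.topology()
    sel_solute = SelectionSpec(mode="site", species=frozenset(config.solute_species))

    # -- stage: simulate ---------------------------------------------------
    trajs = {}
    try:
        for i, t in enumerate(config.temperatures):
            traj = run_nvt(
                config.composition(t),
                top,
                n_sweeps=config.n_sweeps,
                seed=int(
                    np.random.SeedSequence([config.seed, i]).generate_state(1)[0]
                    % (2**31)
                ),
                step_size=config.step_size,
                stride=config.stride,
                cutoff=config.cutoff,
            )
            trajs[t] = traj
            path = outdir / f"traj_T{t:.2f}.xyz"
            write_trajectory(traj, path, "xyz-ext")
            manifest["outputs"][f"trajectory_T{t:.2f}"] = path.name
    except Exception as exc:
        raise PipelineStageError("simulate", exc) from exc
    manifest["stages"].append("simulate")

    # -- stage: rdf + pmf --------------------------------------------------
    pmfs = {}
    try:
        for t, traj in trajs.items():
            r = rdf(
                traj,
                sel_solute,
                sel_solute,
                bin_width=config.rdf_bin_width,
                r_max=config.rdf_r_max,
            )
            pd.DataFrame({"r_nm": r.r, "g": r.g}).to_csv(
                outdir / f"rdf_T{t:.2f}.csv", index=False, float_format="%.8g"
            )
            manifest["outputs"][f"rdf_T{t:.2f}"] = f"rdf_T{t:.2f}.csv"
            pmfs[t] = pmf_from_rdf(r, t)
            pd.DataFrame({"r_nm": pmfs[t].r, "w_kJ_mol": pmfs[t].w}).to_csv(
                outdir / f"pmf_T{t:.2f}.csv", index=False, float_format="%.8g"
            )
            manifest["outputs"][f"pmf_T{t:.2f}"] = f"pmf_T{t:.2f}.csv"
    except Exception as exc:
        raise PipelineStageError("rdf-pmf", exc) from exc
    manifest["stages"].append("rdf-pmf")

    # -- stage: decomposition with block errors ---------------------------
    t_lo, t_mid, t_hi = config.temperatures
    try:
        dec = decompose(pmfs[t_lo], pmfs[t_mid], pmfs[t_hi])

        def _dg_estimator(sub):
            r = rdf(
                sub, sel_solute, sel_solute,
                bin_width=config.rdf_bin_width, r_max=config.rdf_r_max,
            )
            return pmf_from_rdf(r, t_mid).w

        blocks = block_errors(trajs[t_mid], _dg_estimator, n_blocks=config.n_blocks)
        pd.DataFrame(
            {
                "r_nm": dec.r,
                "dG_kJ_mol": dec.dg,
                "dS_kJ_mol_K": dec.ds,
                "dH_kJ_mol": dec.dh,
                "dG_block_sd": blocks.sd,
            }
        ).to_csv(outdir / "decomposition.csv", index=False, float_format="%.8g")
        manifest["outputs"]["decomposition"] = "decomposition.csv"
    except Exception as exc:
        raise PipelineStageError("decomposition", exc) from exc
    manifest["stages"].append("decomposition")

    # -- stage: features ---------------------------------------------------
    try:
        try:
            feats = extract_features(
                pmfs[t_mid],
                window=config.feature_window,
                prominence=config.feature_prominence,
            )
        except FeatureExtractionError as exc:
            # A featureless PMF (e.g. a weakly structured toy run) is a valid,
            # flagged report, not a pipeline failure.
            feats = PMFFeatures.from_extrema(None, None, None, [f"no features: {exc}"])
        feat_row = {
            "system": config.name,
            "CM_r_nm": _fmt(feats.cm[0]) if feats.cm else None,
            "CM_kJ_mol": _fmt(feats.cm[1]) if feats.cm else None,
            "DSP_r_nm": _fmt(feats.dsp[0]) if feats.dsp else None,
            "DSP_kJ_mol": _fmt(feats.dsp[1]) if feats.dsp else None,
            "SSM_r_nm": _fmt(feats.ssm[0]) if feats.ssm else None,
            "SSM_kJ_mol": _fmt(feats.ssm[1]) if feats.ssm else None,
            "dG_u_kJ_mol": _fmt(feats.dg_u),
            "dG_f_kJ_mol": _fmt(feats.dg_f),
            "dG_f2u_kJ_mol": _fmt(feats.dg_f2u),
            "flags": ";".join(feats.flags),
        }
        pd.DataFrame([feat_row]).to_csv(outdir / "features.csv", index=False)
        manifest["outputs"]["features"] = "features.csv"
        manifest["features"] = feat_row
    except Exception as exc:
        raise PipelineStageError("features", exc) from exc
    manifest["stages"].append("features")

    # -- stage: preferential interaction ----------------------------------
    if config.cosolvent_species and any(
        config.counts.get(n, 0) > 0 for n in config.cosolvent_species
    ):
        try:
            traj = trajs[t_mid]
            sel_cos = SelectionSpec(
                mode="site", species=frozenset(config.cosolvent_species)
            )
            sel_wat = SelectionSpec(mode="site", species=frozenset(config.water_species))
            r_max = config.gamma_fallback_cutoff * 1.5
            r_max = min(r_max, traj.box / 2)
            grid = np.arange(config.gamma_dr, r_max + 1e-9, config.gamma_dr)
            prof = gamma_profile(traj, sel_solute, sel_cos, sel_wat, grid)
            cut = select_cutoff(
                prof, window=config.gamma_window, tolerance=config.gamma_tolerance
            )
            forced = cut is None
            if forced:
                cut = min(config.gamma_fallback_cutoff, traj.box / 2)
            est = gamma_estimate(
                traj, sel_solute, sel_cos, sel_wat, cut, n_blocks=config.n_blocks
            )
            pd.DataFrame({"r_nm": prof.r, "gamma": prof.gamma}).to_csv(
                outdir / "gamma_profile.csv", index=False, float_format="%.8g"
            )
            gamma_meta = {
                "cutoff_nm": _fmt(cut),
                "cutoff_forced_fallback": forced,
                "gamma": _fmt(est.value),
                "gamma_sd": _fmt(est.sd),
                "n_blocks": est.n_blocks,
                "flags": est.flags,
            }
            (outdir / "gamma.json").write_text(
                json.dumps(gamma_meta, indent=2, sort_keys=True) + "\n"
            )
            manifest["outputs"]["gamma_profile"] = "gamma_profile.csv"
            manifest["outputs"]["gamma"] = "gamma.json"
            manifest["gamma"] = gamma_meta
        except Exception as exc:
            raise PipelineStageError("gamma", exc) from exc
        manifest["stages"].append("gamma")

    manifest_text = json.dumps(manifest, indent=2, sort_keys=True, default=_fmt) + "\n"
    (outdir / "manifest.json").write_text(manifest_text)
    return manifest
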