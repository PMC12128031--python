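"""PMFs, finite-difference decomposition, feature extraction, block errors."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydrosolv as hs
from hydrosolv.constants import KB
from hydrosolv.pmf import (
    FeatureExtractionError,
    PMFFeatures,
    PMFProfile,
    block_errors,
    decompose,
    enthalpy,
    entropy_finite_difference,
    extract_features,
    pmf_from_rdf,
)
from hydrosolv.structure import RDFResult
from hydrosolv.trajio import SelectionSpec


def profile(r, w, T=298.15):
    w = np.asarray(w, float)
    return PMFProfile(np.asarray(r, float), w, T, np.isfinite(w))


def rdf_of(g, r=None, rho=1.0):
    g = np.asarray(g, float)
    if r is None:
        r = 0.05 + 0.01 * np.arange(g.size)
    return RDFResult(np.asarray(r), g, 0.01, 1, 1, rho, np.zeros_like(g), 1)


class TestPMFFromRDF:
    def test_ideal_gas_gives_zero(self):
        prof = pmf_from_rdf(rdf_of(np.ones(50)), 298.15)
        assert np.allclose(prof.w, 0.0)

    def test_prefactor_is_kbt(self):
        # at 298.15 K the prefactor kB*T is ~2.479 kJ/mol: g = e -> W = -kBT
        prof = pmf_from_rdf(rdf_of([np.e]), 298.15)
        assert prof.w[0] == pytest.approx(-2.479, abs=5e-4)

    def test_inverse_exponential_check(self):
        # g chosen so that W = -4.536 kJ/mol at 298.15 K
        g = np.exp(4.536 / (KB * 298.15))
        prof = pmf_from_rdf(rdf_of([g]), 298.15)
        assert prof.w[0] == pytest.approx(-4.536, abs=1e-9)

    def test_zero_bins_masked(self):
        prof = pmf_from_rdf(rdf_of([0.0, 1.0, 2.0]), 300.0)
        assert not prof.valid[0] and np.isnan(prof.w[0])
        assert prof.valid[1] and prof.valid[2]


class TestFiniteDifference:
    def test_equal_profiles_give_zero_entropy(self):
        r = np.arange(5.0)
        w = [0.0, -1.0, -2.0, -1.0, 0.0]
        ds, valid, dt = entropy_finite_difference(
            profile(r, w, 273.15), profile(r, w, 323.15)
        )
        assert np.allclose(ds[valid], 0.0)
        assert dt == 25.0

    def test_linear_in_t_is_exact(self):
        # W(T) = a + b T -> dS = -b exactly, for any a, b
        r = np.arange(3.0)
        a, b = -2.0, 0.013
        w_of = lambda T: a + b * T
        lo = profile(r, np.full(3, w_of(273.15)), 273.15)
        hi = profile(r, np.full(3, w_of(323.15)), 323.15)
        ds, valid, _ = entropy_finite_difference(lo, hi)
        assert np.allclose(ds[valid], -b, rtol=1e-12)

    def test_hand_arithmetic(self):
        r = np.array([0.0])
        ds, _, _ = entropy_finite_difference(
            profile(r, [-4.0], 273.15), profile(r, [-5.0], 323.15)
        )
        assert ds[0] == pytest.approx(0.02)

    def test_enthalpy_hand_arithmetic(self):
        r = np.array([0.0])
        w = profile(r, [-4.536], 298.15)
        dh = enthalpy(w, np.array([0.02]))
        assert dh[0] == pytest.approx(-4.536 + 298.15 * 0.02, abs=1e-12)
        assert dh[0] == pytest.approx(1.427, abs=1e-3)

    def test_zero_entropy_means_dh_equals_dg(self):
        r = np.arange(4.0)
        w = profile(r, [-1.0, -2.0, 0.5, 0.0])
        assert np.allclose(enthalpy(w, np.zeros(4)), w.w)

    def test_decomposition_identity(self, rng):
        """dH - T dS = dG holds identically on every valid grid point."""
        r = np.arange(0.0, 1.0, 0.02)
        lo = profile(r, rng.normal(size=r.size), 273.15)
        mid = profile(r, rng.normal(size=r.size), 298.15)
        hi = profile(r, rng.normal(size=r.size), 323.15)
        dec = decompose(lo, mid, hi)
        resid = dec.dh[dec.valid] - dec.temperature * dec.ds[dec.valid] - dec.dg[dec.valid]
        assert np.all(np.abs(resid) < 1e-12)
        assert dec.delta_t == 25.0
        assert dec.assumes_constant_cv

    def test_grid_mismatch_rejected(self):
        with pytest.raises(hs.HydrosolvError):
            entropy_finite_difference(
                profile(np.arange(3.0), np.zeros(3), 273.15),
                profile(np.arange(4.0), np.zeros(4), 323.15),
            )


class TestExtractFeatures:
    def synthetic_double_well(self, cm_v, dsp_v, ssm_v):
        """Piecewise-cosine PMF with exact extrema at 0.4, 0.6, 0.8 nm."""
        r = np.arange(0.3, 1.2, 0.005)
        w = np.empty_like(r)
        for i, x in enumerate(r):
            if x < 0.6:
                # cosine arc from dsp at 0.2-away up through cm at 0.4
                w[i] = cm_v + (dsp_v - cm_v) * 0.5 * (1 - np.cos(np.pi * (x - 0.4) / 0.2))
            elif x < 0.8:
                w[i] = ssm_v + (dsp_v - ssm_v) * 0.5 * (1 - np.cos(np.pi * (x - 0.8) / 0.2))
            else:
                w[i] = ssm_v + (0.0 - ssm_v) * 0.5 * (1 - np.cos(np.pi * np.clip((x - 0.8) / 0.4, 0, 1)))
        return profile(r, w)

    # the three self-consistent hydrocarbon-in-water rows: (CM, DSP, SSM)
    # and their published differences (dG_u, dG_f, dG_f2u)
    @pytest.mark.parametrize(
        "extrema, diffs",
        [
            ((-4.536, 0.701, -0.169), (5.237, -0.870, 4.367)),  # branched C5 solute
            ((-4.589, 0.669, -0.523), (5.258, -1.192, 4.066)),  # cyclic C6 solute
            ((-6.846, -4.990, -3.202), (1.856, 1.788, 3.644)),  # linear C6 solute
        ],
    )
    def test_difference_identities(self, extrema, diffs):
        cm, dsp, ssm = extrema
        feats = PMFFeatures.from_extrema((0.4, cm), (0.6, dsp), (0.8, ssm))
        assert feats.dg_u == pytest.approx(diffs[0], abs=5e-4)
        assert feats.dg_f == pytest.approx(diffs[1], abs=5e-4)
        assert feats.dg_f2u == pytest.approx(diffs[2], abs=5e-4)
        # internal identity: dG_u + dG_f = dG_f2u
        assert feats.dg_u + feats.dg_f == pytest.approx(feats.dg_f2u, abs=1e-12)

    def test_constructed_profile_recovered(self):
        pmf = self.synthetic_double_well(-4.5, 0.7, -0.2)
        feats = extract_features(pmf, window=1, prominence=0.05)
        assert feats.cm[0] == pytest.approx(0.4, abs=0.01)
        assert feats.cm[1] == pytest.approx(-4.5, abs=1e-6)
        assert feats.dsp[0] == pytest.approx(0.6, abs=0.01)
        assert feats.dsp[1] == pytest.approx(0.7, abs=1e-6)
        assert feats.ssm[0] == pytest.approx(0.8, abs=0.01)
        assert feats.ssm[1] == pytest.approx(-0.2, abs=1e-6)

    def test_offset_invariance(self):
        """Adding a constant to W leaves all feature differences unchanged."""
        base = extract_features(self.synthetic_double_well(-4.5, 0.7, -0.2), window=1)
        shifted_profile = self.synthetic_double_well(-4.5, 0.7, -0.2)
        shifted_profile.w += 3.21
        shifted = extract_features(shifted_profile, window=1)
        assert shifted.dg_u == pytest.approx(base.dg_u, abs=1e-10)
        assert shifted.dg_f == pytest.approx(base.dg_f, abs=1e-10)
        assert shifted.dg_f2u == pytest.approx(base.dg_f2u, abs=1e-10)

    def test_missing_barrier_flagged(self):
        # single-well PMF: CM exists, no DSP/SSM -> differences absent
        r = np.arange(0.3, 1.2, 0.005)
        w = -3.0 * np.exp(-((r - 0.45) ** 2) / (2 * 0.05**2))
        feats = extract_features(profile(r, w), window=1)
        assert feats.cm is not None
        assert feats.dsp is None and feats.ssm is None
        assert feats.dg_u is None and feats.dg_f is None and feats.dg_f2u is None
        assert any("low-confidence" in f for f in feats.flags)

    def test_no_minimum_is_an_error(self):
        r = np.arange(0.3, 1.0, 0.01)
        with pytest.raises(FeatureExtractionError):
            extract_features(profile(r, np.linspace(3.0, 0.0, r.size)), window=1)

    def test_search_restricted_to_region_of_global_minimum(self):
        # a spurious shallow well separated by a sampling gap must be ignored
        r = np.arange(0.3, 1.2, 0.01)
        w = 2.0 - 2.0 * np.exp(-((r - 0.9) ** 2) / (2 * 0.06**2))
        w[:10] = 1.5  # disconnected featureless ledge above the well
        w[10:15] = np.nan  # gap (unsampled bins)
        feats = extract_features(profile(r, w), window=1)
        assert feats.cm[0] == pytest.approx(0.9, abs=0.02)


class TestBlockErrors:
    def _replicated_traj(self):
        sp = hs.ParticleSpecies("A", 0.0, 0.0)
        top = hs.Topology.from_counts({sp: 4})
        pos = np.array([[0.2] * 3, [0.8] * 3, [1.4] * 3, [0.5, 1.1, 0.3]])
        frames = [hs.Frame(pos.copy(), 2.0, step=i) for i in range(10)]
        return hs.Trajectory(top, frames)

    def test_identical_frames_have_zero_sd(self):
        traj = self._replicated_traj()
        sel = SelectionSpec(species=frozenset({"A"}))

        def estimator(sub):
            return hs.rdf(sub, sel, sel, bin_width=0.1).g

        prof = block_errors(traj, estimator, n_blocks=5)
        assert np.allclose(prof.sd, 0.0)

    def test_textbook_sample_sd(self):
        sp = hs.ParticleSpecies("A", 0.0, 0.0)
        top = hs.Topology.from_counts({sp: 1})
        frames = [hs.Frame(np.full((1, 3), 0.1 * (i + 1)), 2.0, step=i) for i in range(5)]
        traj = hs.Trajectory(top, frames)
        # estimator returns the hand-set block constants 1..5
        prof = block_errors(
            traj, lambda sub: np.array([float(sub.frames[0].step + 1)]), n_blocks=5
        )
        assert prof.sd[0] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))
        assert prof.sd[0] == pytest.approx(1.5811388, abs=1e-6)

    def test_one_frame_per_block_boundary(self):
        traj = self._replicated_traj()
        prof = block_errors(
            traj, lambda sub: np.array([float(sub.n_frames)]), n_blocks=traj.n_frames
        )
        assert prof.block_values.shape[0] == traj.n_frames
        assert np.all(prof.block_values == 1.0)

    def test_too_few_frames_rejected(self):
        traj = self._replicated_traj()
        with pytest.raises(hs.HydrosolvError):
            block_errors(traj, lambda sub: np.zeros(1), n_blocks=traj.n_frames + 1)


class TestDiluteLimitOracle:
    def test_pmf_matches_pair_potential(self, lj_pair_traj, lj_pair_system):
        """Statistical-mechanics link between the sampler and the PMF chain:
        for two dilute LJ particles, W(r) = -kBT ln g(r) reproduces the
        (truncated-shifted) pair potential within 3 block sd."""
        a, b, top, comp = lj_pair_system
        sel_a = SelectionSpec(species=frozenset({"A"}))
        sel_b = SelectionSpec(species=frozenset({"B"}))
        bw = 0.05
        res = hs.rdf(lj_pair_traj, sel_a, sel_b, bin_width=bw)
        pmf = pmf_from_rdf(res, comp.temperature)

        def estimator(sub):
            return pmf_from_rdf(
                hs.rdf(sub, sel_a, sel_b, bin_width=bw), comp.temperature
            ).w

        blocks = block_errors(lj_pair_traj, estimator, n_blocks=5)
        cutoff = min(1.2, lj_pair_traj.box / 2)
        sig, eps = hs.combine_lorentz_berthelot(a, b)
        u = np.array(
            [hs.pair_energy(x, sig, eps, cutoff=cutoff, shift=True) for x in pmf.r]
        )
        window = (pmf.r > 0.3) & (pmf.r < 0.95) & pmf.valid
        ok = window & np.all(np.isfinite(blocks.block_values), axis=0)
        assert ok.sum() >= 8
        resid = np.abs(pmf.w[ok] - u[ok])
        assert np.all(resid <= 3 * blocks.sd[ok] + 0.05)
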