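"""Pair structure: g(r) estimator, coordination numbers, shell angles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydrosolv as hs
from hydrosolv.structure import (
    RDFResult,
    StructureError,
    coordination_number,
    first_minimum,
    rdf,
    shell_angle_distribution,
)
from hydrosolv.trajio import SelectionSpec


def synthetic_rdf(r, g, rho=1.0):
    r = np.asarray(r, float)
    g = np.asarray(g, float)
    bw = float(r[1] - r[0])
    return RDFResult(r, g, bw, 1, 1, rho, np.zeros_like(g), 1)


class TestRDF:
    def test_ideal_gas_cross_species_is_flat(self, ideal_gas_traj):
        """Non-interacting mixture: cross-species g(r)=1 within
        3/sqrt(counts) per bin (the estimator's exact ideal null)."""
        res = rdf(
            ideal_gas_traj,
            SelectionSpec(species=frozenset({"C"})),
            SelectionSpec(species=frozenset({"W"})),
            bin_width=0.05,
        )
        # skip the innermost poorly-populated bins
        keep = res.counts >= 30
        tol = 3.0 / np.sqrt(res.counts[keep])
        assert np.all(np.abs(res.g[keep] - 1.0) <= tol)

    def test_ideal_gas_same_species_finite_n_null(self, ideal_gas_traj):
        """Same-selection g(r): the histogram estimator normalised with
        rho = N/V has ideal-gas expectation (N-1)/N, approached within 3 sigma."""
        res = rdf(
            ideal_gas_traj,
            SelectionSpec(species=frozenset({"W"})),
            SelectionSpec(species=frozenset({"W"})),
            bin_width=0.05,
        )
        null = (res.n_target - 1) / res.n_target
        keep = res.counts >= 30
        tol = 3.0 / np.sqrt(res.counts[keep])
        assert np.all(np.abs(res.g[keep] - null) <= tol)

    def test_two_particles_single_bin(self):
        a = hs.ParticleSpecies("A", 0.0, 0.0)
        b = hs.ParticleSpecies("B", 0.0, 0.0)
        top = hs.Topology.from_molecules([[a], [b]])
        frame = hs.Frame(np.array([[0.5, 0.5, 0.5], [0.5, 0.5, 1.13]]), 2.0)
        traj = hs.Trajectory(top, [frame])
        res = rdf(
            traj,
            SelectionSpec(species=frozenset({"A"})),
            SelectionSpec(species=frozenset({"B"})),
            bin_width=0.01,
        )
        assert res.counts.sum() == 1
        hit = np.flatnonzero(res.counts)
        assert hit.size == 1
        assert abs(res.r[hit[0]] - 0.63) < 0.01

    def test_brute_force_bin_counts(self, rng):
        sp = hs.ParticleSpecies("A", 0.0, 0.0)
        top = hs.Topology.from_counts({sp: 20})
        box = 2.0
        frames = [
            hs.Frame(rng.uniform(0, box, size=(20, 3)), box) for _ in range(5)
        ]
        traj = hs.Trajectory(top, frames)
        sel = SelectionSpec(species=frozenset({"A"}))
        res = rdf(traj, sel, sel, bin_width=0.05)
        edges = np.arange(res.r.size + 1) * 0.05
        brute = np.zeros(res.r.size)
        for f in frames:
            for i in range(20):
                for j in range(i + 1, 20):
                    d = f.positions[i] - f.positions[j]
                    d -= box * np.round(d / box)
                    r = np.linalg.norm(d)
                    k = int(r // 0.05)
                    if k < brute.size and r < edges[-1]:
                        brute[k] += 1
        assert np.array_equal(res.counts, brute)

    def test_pair_count_conservation(self, ideal_gas_traj):
        """Raw bin counts sum to the number of in-range pair observations."""
        res = rdf(
            ideal_gas_traj,
            SelectionSpec(species=frozenset({"C"})),
            SelectionSpec(species=frozenset({"W"})),
            bin_width=0.05,
        )
        coords_c = hs.resolve_selection(
            ideal_gas_traj, SelectionSpec(species=frozenset({"C"}))
        ).points
        coords_w = hs.resolve_selection(
            ideal_gas_traj, SelectionSpec(species=frozenset({"W"}))
        ).points
        box = ideal_gas_traj.box
        in_range = 0
        for f in range(coords_c.shape[0]):
            d = coords_c[f][:, None, :] - coords_w[f][None, :, :]
            d -= box * np.round(d / box)
            r = np.sqrt((d**2).sum(-1))
            in_range += int((r < res.r_max).sum())
        assert res.counts.sum() == in_range

    def test_translation_and_frame_relabel_invariance(self, rng):
        sp = hs.ParticleSpecies("A", 0.0, 0.0)
        top = hs.Topology.from_counts({sp: 10})
        box = 2.0
        frames = [hs.Frame(rng.uniform(0, box, (10, 3)), box) for _ in range(4)]
        traj = hs.Trajectory(top, frames)
        sel = SelectionSpec(species=frozenset({"A"}))
        base = rdf(traj, sel, sel, bin_width=0.05)
        shifted = hs.Trajectory(
            top,
            [hs.Frame(np.mod(f.positions + box, box), box) for f in frames[::-1]],
        )
        moved = rdf(shifted, sel, sel, bin_width=0.05)
        assert np.allclose(base.g, moved.g)

    def test_r_max_beyond_half_box_rejected(self, ideal_gas_traj):
        sel = SelectionSpec(species=frozenset({"W"}))
        with pytest.raises(StructureError):
            rdf(ideal_gas_traj, sel, sel, r_max=ideal_gas_traj.box)


class TestCoordinationNumber:
    def test_ideal_gas_closed_form(self):
        r = np.arange(0.005, 1.0, 0.01)
        res = synthetic_rdf(r, np.ones_like(r), rho=2.0)
        n = coordination_number(res, 0.8)
        assert n == pytest.approx((4 / 3) * np.pi * 2.0 * 0.8**3, rel=5e-4)

    def test_below_first_bin_is_zero(self):
        r = np.arange(0.105, 1.0, 0.01)
        res = synthetic_rdf(r, np.ones_like(r))
        assert coordination_number(res, 0.05) == 0.0

    def test_rectangular_peak_hand_integral(self):
        r = np.arange(0.005, 1.0, 0.01)
        g = np.where((r >= 0.3) & (r < 0.5), 2.0, 0.0)
        res = synthetic_rdf(r, g, rho=1.5)
        # 4 pi rho * 2 * (r^3/3) on [0.3, 0.5]
        expected = 4 * np.pi * 1.5 * 2.0 * (0.5**3 - 0.3**3) / 3
        assert coordination_number(res, 0.9) == pytest.approx(expected, rel=2e-3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), r_hi=st.floats(0.2, 0.9))
    def test_monotone_in_cutoff(self, seed, r_hi):
        rng = np.random.default_rng(seed)
        r = np.arange(0.005, 1.0, 0.01)
        res = synthetic_rdf(r, rng.uniform(0, 3, r.size))
        assert coordination_number(res, r_hi) <= coordination_number(res, 0.95) + 1e-12


class TestFirstMinimum:
    def test_monotone_profile_has_none(self):
        r = np.arange(0.005, 1.0, 0.01)
        assert first_minimum(synthetic_rdf(r, np.linspace(0, 2, r.size))) is None

    def test_flat_profile_has_none(self):
        r = np.arange(0.005, 1.0, 0.01)
        assert first_minimum(synthetic_rdf(r, np.ones_like(r))) is None

    def test_constructed_extrema(self):
        r = np.arange(0.005, 1.2, 0.01)
        g = (
            1.0
            + 1.5 * np.exp(-((r - 0.5) ** 2) / (2 * 0.05**2))
            - 0.5 * np.exp(-((r - 0.8) ** 2) / (2 * 0.05**2))
        )
        found = first_minimum(synthetic_rdf(r, g))
        assert found == pytest.approx(0.8, abs=0.02)


class TestShellAngles:
    def _traj_with_probes(self, probe_pos, box=4.0):
        s = hs.ParticleSpecies("S", 0.0, 0.0)
        p = hs.ParticleSpecies("P", 0.0, 0.0)
        n = probe_pos.shape[0]
        top = hs.Topology.from_molecules([[s]] + [[p]] * n)
        pos = np.vstack([[box / 2, box / 2, box / 2], probe_pos])
        return hs.Trajectory(top, [hs.Frame(pos, box)])

    def test_parallel_axes_pile_at_one(self):
        centre = 2.0
        probes = centre + np.array([[0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.5]])
        traj = self._traj_with_probes(probes)
        axes = (probes - centre)[None, :, :]  # axis parallel to displacement
        dist = shell_angle_distribution(
            traj,
            SelectionSpec(species=frozenset({"S"})),
            SelectionSpec(species=frozenset({"P"})),
            axes,
            shell=(0.0, 1.0),
            n_bins=10,
        )
        assert dist.n_observations == 3
        assert dist.density[-1] > 0
        assert np.all(dist.density[:-1] == 0)
        # normalized over [-1, 1]
        width = dist.cos_theta[1] - dist.cos_theta[0]
        assert dist.density.sum() * width == pytest.approx(1.0)

    def test_isotropic_axes_uniform(self, rng):
        n = 400
        theta = np.arccos(rng.uniform(-1, 1, n))
        phi = rng.uniform(0, 2 * np.pi, n)
        shell_pts = 2.0 + 0.5 * np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        traj = self._traj_with_probes(shell_pts)
        axes = rng.normal(size=(1, n, 3))
        dist = shell_angle_distribution(
            traj,
            SelectionSpec(species=frozenset({"S"})),
            SelectionSpec(species=frozenset({"P"})),
            axes,
            shell=(0.0, 1.0),
            n_bins=8,
        )
        # uniform density 0.5 within sampling noise
        per_bin = n / 8
        tol = 3 * np.sqrt(per_bin) / per_bin * 0.5
        assert np.all(np.abs(dist.density - 0.5) <= tol)

    def test_hand_trigonometry(self):
        probes = np.array([[2.5, 2.0, 2.0], [2.0, 2.6, 2.0], [2.0, 2.0, 2.4]])
        traj = self._traj_with_probes(probes)
        # axes at known angles to the radial direction
        axes = np.array(
            [[[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [1.0, 0.0, 1.0]]]
        )
        dist = shell_angle_distribution(
            traj,
            SelectionSpec(species=frozenset({"S"})),
            SelectionSpec(species=frozenset({"P"})),
            axes,
            shell=(0.0, 1.0),
            n_bins=4,
        )
        # cos values: +1, -1, cos(45 deg) -> bins 3, 0, 3
        assert dist.n_observations == 3
        expected = np.zeros(4)
        expected[3] = 2 / (3 * 0.5)
        expected[0] = 1 / (3 * 0.5)
        assert np.allclose(dist.density, expected)

    def test_axis_from_site_labels(self):
        s = hs.ParticleSpecies("S", 0.0, 0.0)
        o = hs.ParticleSpecies("O", 0.0, 0.0, mass=16.0)
        h = hs.ParticleSpecies("H", 0.0, 0.0, mass=1.0)
        top = hs.Topology.from_molecules([[s], [o, h]])
        box = 4.0
        pos = np.array([[2.0, 2.0, 2.0], [2.5, 2.0, 2.0], [2.6, 2.0, 2.0]])
        traj = hs.Trajectory(top, [hs.Frame(pos, box)])
        dist = shell_angle_distribution(
            traj,
            SelectionSpec(species=frozenset({"S"})),
            SelectionSpec(mode="central-site", species=frozenset({"O", "H"}), central_site="O"),
            ("O", "H"),
            shell=(0.0, 1.0),
            n_bins=10,
        )
        # O->H axis points along the S->O displacement: cos(theta) = 1
        assert dist.n_observations == 1
        assert dist.density[-1] > 0
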