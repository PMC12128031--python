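# Methods

This note records the models, conventions and numerical choices behind
hydrosolv, and what its green tests do and do not establish.

## The toy sampler and what it emulates

The package targets the analysis chain used to characterise hydrophobic
association in osmolyte solutions: solute–solute pair structure, potentials
of mean force and their temperature decomposition, preferential interaction
coefficients, solvation free energies, and protein-style order parameters.
The original data for such analyses are hundreds of nanoseconds of all-atom
MD for ~4000-molecule systems; the built-in generator replaces them with a
seedable Metropolis Monte-Carlo sampler at desk scale so that every stage
can be exercised and statistically validated in minutes.

The sampler works on mixtures of rigid molecules in a cubic periodic box at
fixed N, V, T. The default systems mirror the modelled compositions in
miniature: ~10 "solute" particles plus a few hundred "water"/"cosolvent"
particles, with per-site Lennard-Jones parameters taken from the same
united-atom/3–4-site parameter families the full systems use (σ ≈ 0.3–0.4 nm,
ε ≈ 0.2–0.8 kJ/mol), at three temperatures 273.15/298.15/323.15 K
(T ± 25 K around ambient). Species are single-site in the engine; the data
model keeps molecule grouping so multi-site rigid molecules remain
representable for the I/O and analysis layers (e.g. hand-built probes for
angle distributions), but the sampler refuses to generate them.

Deliberate simplifications, hence what a green test does **not** establish:

* no molecular dynamics — single-molecule rigid translations with the
  Metropolis rule; dynamics and time correlations are meaningless here;
* no Ewald electrostatics — plain truncated Coulomb, charges off by default
  in the bundled configs; polar-solvent physics (hydrogen-bond networks,
  dielectric screening) is not emulated;
* truncated-and-shifted LJ inside the sampler (cutoff 1.2 nm, mirroring a
  12.2 Å single-range convention) with no tail corrections;
* densities well below aqueous (≈6 nm⁻³ vs ≈33 nm⁻³ for water) so that the
  smoke-scale pipeline converges in minutes.

Green statistical tests therefore establish *estimator correctness and
sampler consistency* (g → 1 for ideal mixtures, W(r) → pair potential at
dilution, Γ → 0 on mixing nulls, TI ↔ Widom), not any claim about real
osmolyte solutions.

### Engine conventions

* Metropolis acceptance min(1, e^(−ΔU/k_B T)); one sweep = one attempted
  move per molecule; maximum displacement auto-tuned toward 40 % acceptance
  during the equilibration phase (first 20 % of sweeps, discarded) and then
  frozen, so production sampling obeys detailed balance.
* Incremental move energies are audited against from-scratch recomputation
  (tested to 1e−9 relative).
* Placement is random sequential insertion with a 0.85 σ_ij soft veto and
  bounded retries; failure raises an initialization error.
* Identical (composition, parameters, seed) gives bit-identical
  trajectories; per-λ and per-temperature streams are derived from the master
  seed via `SeedSequence` and kept below 2³¹.
* The public `pair_energy`/`total_energy` default to *unshifted* truncation
  (so the textbook identities hold exactly: U(σ) = 0, U(2^{1/6}σ) = −ε);
  the sampler and the Widom/TI Hamiltonians use the shifted form. Pairs of
  interacting sites closer than 0.1 σ_ij are treated as unphysical overlaps
  by the public energy routines.

## g(r), coordination numbers, shells

Distances are minimum-image; all pair functions exclude same-molecule
pairs. The histogram estimator normalises by frames × N_ref × ρ_target ×
ideal shell volume, with unordered pairs counted once and the normalisation
halved when reference and target selections coincide. Note the finite-N
consequence: for a same-species selection the ideal-gas expectation of this
estimator is (N−1)/N, not 1 — tests against the homogeneous null use the
cross-species estimator (expectation exactly 1) or the corrected null.

Defaults: bin width 0.01 nm (resolves the ~0.28 nm water-structure peak
with >20 bins); coordination numbers by midpoint sums consistent with the
histogram (trapezoid switchable); extremum detection on a centred moving
average (window 5 bins) with prominence 0.05 — a deliberately permissive
setting that still reports features for weakly structured profiles, flagged
rather than suppressed. When no prominent first maximum exists,
`first_minimum` returns absence (a value, not an error) and callers fall
back to a fixed cutoff, conventionally 1 nm for featureless solute–solute
profiles.

Shell-resolved orientation distributions require an explicit axis
definition per probe molecule — either a pair of site labels (a dipole-like
proxy) or explicit vectors — because single-site probes carry no intrinsic
orientation; the choice is a caller parameter, recorded with the output.

## PMFs and the finite-difference decomposition

W(r) = −k_B T ln g(r) with k_B = 0.008314462618 kJ·mol⁻¹·K⁻¹ (so
k_B T ≈ 2.479 kJ/mol at 298.15 K is reproduced, never hard-coded). Bins
with g = 0 are masked rather than clipped; feature extraction searches only
the largest contiguous valid region containing the global minimum, which
avoids manufacturing barriers at sampling gaps.

ΔS by central difference over (T−ΔT, T+ΔT), ΔH = ΔG + TΔS; the identity
ΔH − TΔS − ΔG = 0 holds to machine precision by construction and the
central difference is exact for ΔG linear in T (the strict constant-C_v
reading). ΔT defaults to 25 K; the constant-heat-capacity assumption is
carried as metadata on every decomposition. Uncertainties are per-grid-point
sample standard deviations over five contiguous frame blocks.

CM/DSP/SSM are located on the smoothed profile and their values read from
the raw one; differences obey ΔG_u + ΔG_f = ΔG_f→u identically. Profiles
without a genuine barrier (monotone rise past the contact minimum — the
near-asymptotic linear-alkane case) yield absent DSP/SSM and flagged,
absent differences instead of fabricated ones.

## Preferential interaction

Γ(r) follows the excess-counting definition with one reference point per
molecule (first site by default, COM optional) and "distance from the
solute" implemented as distance to the nearest solute selection point — the
reproducible reading of a surface distance for point solutes. The bracket
is evaluated per frame and then averaged (not ratio-of-averages); frames
where the bulk-water denominator vanishes at some r are excluded at that r
and tallied, never silently dropped. The local/bulk cutoff r* is the
smallest r whose trailing-window Γ range falls below tolerance; absence of
a plateau is a diagnostic and callers may force a cutoff. The uncertainty
on Γ(r*) is a five-block standard deviation, chosen by analogy with the
PMF error convention since no error model is canonical here; outputs label
it as such.

## Thermodynamic integration

The coupling is strictly linear, V(λ) = (1−λ)V₀ + λV₁, with the tagged
solute non-interacting in state 1, so dV/dλ = −U_solute at full coupling.
Because the λ path runs from solvated (0) to decoupled (1), the switching
integral equals minus the solvation free energy; `TIResult` stores both and
reports ΔG_s = −∫⟨dV/dλ⟩dλ so that ΔG_s < 0 means favourable solvation and
the value is directly comparable to the Widom excess chemical potential
−k_B T ln⟨e^{−ΔU/k_B T}⟩ (evaluated with the same shifted Hamiltonian).
Quadrature is trapezoidal (exact for linear profiles, error bounded and
propagated in quadrature from five-block per-λ standard errors); the
conventional production grid is 21 equispaced points, scaled down in tests.

**Endpoint caveat.** With a linear coupling and an r⁻¹² core, the
λ → 1 integrand −⟨U_solute⟩_λ has a diverging mean/variance: near the
decoupled endpoint the free solute occasionally overlaps bath particles and
contributes astronomically negative samples. This is the well-known
hard-core decoupling pathology that soft-core couplings exist to cure; the
coupling here is kept in its printed linear form deliberately. In the dilute
toy regime overlaps are rare, but when one is sampled the per-λ block error
inflates accordingly — the TI ↔ Widom consistency check is then dominated
by that honest, large σ. The quadrature and error-propagation machinery is
therefore validated tightly on synthetic dV/dλ profiles (linear and
polynomial, hand-integrable), while the sampled cross-check establishes
consistency only at the precision the linear endpoint permits. Null solutes
(ε = 0, q = 0) give exactly zero at every λ, and that identity is tested
exactly.

## Protein-style observables

* RMSD uses optimal rigid superposition (weighted Kabsch via SciPy's
  rotation alignment). The unfitted variant exists behind
  `superpose=False` for literal comparability, but without superposition
  RMSD conflates diffusion with conformational change, so fitting is the
  default. Mass weighting is the default weighting.
* R_g is the square-rooted, mass-normalised second moment — the standard
  definition.
* SASA is surface-point sampling on a deterministic Fibonacci lattice
  (default 960 points) over spheres inflated by the probe radius (default
  0.14 nm): a Shrake–Rupley-style contract that matches closed-form sphere
  and two-sphere cap areas to better than 1 % at the default lattice and
  converges under point doubling.
* Hydrogen bonds use a conventional geometric criterion — donor–acceptor
  distance ≤ 0.35 nm and D–H···A within 30° of linearity — stated in the
  output because no single criterion is canonical.
* The free-energy landscape bins two observable series (conventionally R_g
  and SASA) on a 50×50 grid over the observed range and reports
  F = −k_B T ln(P/P_max): zero at the global minimum, masked where empty,
  single-cell degenerate landscapes valid but flagged.

## Pipeline and provenance

The pipeline driver simulates at T − ΔT, T, T + ΔT (seed-derived streams),
chains g(r) → W(r) → decomposition → features, adds block errors, and runs
the Γ stage when cosolvent is present. Every artifact directory carries a
`manifest.json` with the canonical config, its SHA-256 hash, the seed and
the artifact list; identical configs and seeds reproduce the manifest
byte-for-byte. A stage failure aborts with the stage name while preserving
artifacts already written; an extraction that merely finds no PMF features
is reported as a flagged, feature-less row rather than a failure. The
bundled demo config (10 solutes + 400 bath particles, 4 nm box, 600 sweeps,
0.03 nm RDF bins) is generated programmatically and is sized for minutes,
not convergence.

## Known limitations

* The sampler is single-site/rigid-translation only; no bonded terms,
  orientational moves, thermostat dynamics or multi-site water.
* Linear-coupling TI near λ = 1 has the endpoint-variance pathology above.
* Block errors assume approximately independent blocks; at smoke scale
  blocks are short and the five-block σ is itself noisy.
* The demo's PMF features sit at the noise level by design; quantitative
  CM/DSP/SSM work needs longer runs and finer bins than the demo defaults.
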