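# Methods

## Scope and model

The package estimates *relative* binding affinities of peptide substrates
for a kinase by rescoring snapshot ensembles of the complex with an
implicit-solvent end-state model, and connects those estimates to
steady-state kinetics through a thermodynamic-cycle argument: if the
perturbation (a point mutation or truncation near the phosphorylation
site) shifts the enzyme–substrate complex and the rate-determining
transition state similarly, then the calculated shift in binding free
energy ΔΔG(E→ES) tracks the experimental shift in activation free energy
ΔΔG(E→TS) obtained from catalytic efficiencies. The package never
simulates dynamics; it consumes ensembles (multi-model PDB) produced
elsewhere or generated synthetically.

## Kinetics conversion

ΔΔG(E→ES) = RT ln(K_M,variant/K_M,ref) treats K_M as a dissociation
constant, valid in the quasi-equilibrium regime (k₋₁ ≫ k_cat); this is an
assumption of the method, stated rather than hidden. ΔΔG(E→TS) =
RT ln(eff_ref/eff_variant) uses V_max/K_M, proportional to k_cat/K_M for a
fixed enzyme preparation, so the unknown enzyme mass cancels in the ratio.
T defaults to 298.15 K; both shifts are antisymmetric and additive by
construction, and the reference row is exactly zero. Rows with
non-positive constants (e.g. "negligible activity" entries) are rejected
as domain errors rather than silently dropped.

## MM/GBSA engine

Single-trajectory protocol: each component is X(complex) − X(receptor) −
X(ligand), all three evaluated on coordinates cut from the same complex
frame. Bonded terms therefore cancel identically; the scorer verifies that
no bonded term crosses the partition and then reports ΔE_internal = 0
exactly (the floating-point residue would otherwise be ~1e-13 noise).
The entropy slot exists in the data model but is fixed at zero: reported
ΔG values are enthalpy-like and comparable only between similar systems,
which is exactly how they are used (ΔΔG against a reference).

Term by term:

- **Electrostatics** — Coulomb sum with k_C = 332.0636 kcal·Å/(mol·e²),
  no distance cutoff (cutoffs belong to the dynamics, not the rescoring);
  1-2/1-3 pairs excluded via the bond graph, 1-4 pairs scaled by a single
  configurable factor (default 1.0).
- **van der Waals** — 12-6 Lennard-Jones, ε_ij = √(ε_iε_j),
  r_min,ij = r_min,i/2 + r_min,j/2 from the half-r_min parameter fields.
- **Polar solvation** — generalized Born in Still's pairwise form with
  self terms, f_GB = √(r² + R_iR_j e^(−r²/4R_iR_j)). Effective radii use
  pairwise HCT descreening integrals (neighbour scaling S = 1) with
  OBC-II tanh rescaling, α = 1.0, β = 0.8, γ = 4.85, intrinsic-radius
  offset 0.09 Å. Solvent dielectric 78.5, interior 1.0, both
  configurable. The GB flavour is a genuine design choice — published
  MM/GBSA numbers depend on the exact variant and radii set of the MD
  engine that produced them — so it is isolated behind `GBSettings`, and
  quantitative reproduction of third-party absolute ΔG tables is
  explicitly not claimed.
- **Nonpolar solvation** — γ·SASA with γ = 0.00542 kcal/mol/Å² (optional
  constant offset, default 0). SASA is Shrake–Rupley quadrature on a
  deterministic golden-spiral point set (default 960 points ≈ 0.5%
  accuracy on a sphere), probe 1.4 Å, using the per-atom GB radii as the
  van der Waals radii.

Ensemble averaging selects frames deterministically (equilibration skip,
then a stride or a uniform spread to a target count — no randomness), and
reports per-component mean ± SD. SDs are population SDs (ddof = 0) of the
per-snapshot values; the convention is stated because ± values in
published tables of this kind are rarely defined.

## Trajectory statistics

Superposition is least-squares (SVD-based, proper rotation enforced);
degenerate fits (< 3 atoms or collinear selections) are errors, not
warnings. RMSD series superpose each frame on the reference selection
(backbone = N, CA, C, O) before measuring.

Hydrogen bonds use the heavy-atom donor–acceptor distance criterion
(< 3.5 Å) with no angular term — deliberately weaker than DSSP-style
definitions, but it is the criterion the occupancy statistics are defined
by, and hydrogens need not be present. Two denominators are used on
purpose: occupancy is a percentage of all frames; the conditional mean ±
SD distance uses qualifying frames only. Because the conditional mean is
bounded by the cutoff, a reported mean above 3.5 Å can only arise from
statistics taken over all frames; the `HBondStat.over_cutoff_mean` flag
marks such entries when they are requested for comparison
(`--include-over-cutoff`), and the default output excludes them.
Which atoms may donate or accept is an editable packaged TSV (wildcard
rules over residue/atom names), since no universal rule is assumed.
Hydrophobic contacts reuse the machinery with a 4.5 Å carbon–carbon
cutoff; "stable" means occupancy ≥ 50% in both cases.

Candidate-pair enumeration pre-screens receptor–ligand pairs by minimum
distance over (optionally strided) frames; at stride 1 it is a strict
superset of every qualifying pair at any cutoff below the screen
distance, which is property-tested.

## Correlation and histidine states

R² is the squared Pearson correlation of the paired shifts, identical to
the OLS coefficient of determination with intercept; the experimental
axis is ΔΔG(E→TS), so the fitted slope/intercept read as a predictor from
calculation to experiment. Each of the nine (tautomer@−3, tautomer@−2)
assignments yields a 7-point dataset (reference + four non-histidine
mutants + the chosen pair, reference anchored at the origin); the grid is
evaluated exhaustively and ties are reported as a set of maximizers, never
broken silently. The full model appends the three truncated peptides
(10 points).

## Synthetic data: what it emulates and what it does not

`make_toy_complex` builds residue-grouped, fully parameterized mini
complexes (two strands ~8 Å apart) with prescribed charged donor/acceptor
contact pairs; parameters are drawn inside common force-field ranges
(charges ±0.3 e backbone, ±0.5–1.0 e contacts; ε 0.05–0.2 kcal/mol; radii
1.2–2.0 Å). `make_ensemble` adds isotropic Gaussian noise (σ defaults per
test, typically 0.15–0.25 Å, the scale of a well-equilibrated backbone
fluctuation) and then *constructs* each scheduled pair's distance inside
or outside the criterion in an exactly sized, seed-shuffled frame subset,
with guard margins (cutoff ± 0.2 Å) so float noise cannot flip a frame.
Realized occupancies therefore equal their targets exactly at the stated
frame counts, and recount tests are sharp; a `sampled` mode provides
binomial realism instead.

What passing synthetic tests show: the kernels, counting rules,
cancellation properties and orderings are implemented correctly. What
they do not show: agreement with any particular force field, water model
or production trajectory — toy ensembles have no correlated motions, no
rotamer dynamics, and no solvent structure.

## Numerical choices and degenerate inputs

- Coincident interacting atoms raise singularity errors (Coulomb, LJ, GB
  radii); excluded 1-2/1-3 pairs may coincide harmlessly.
- The OBC no-neighbour limit returns the offset-corrected intrinsic
  radius (R − 0.09 Å); with the offset set to 0 it returns R exactly.
- SASA is deterministic for fixed point count; rigid-motion invariance
  holds to quadrature tolerance (≤ 0.5% at 960 points).
- Snapshot selection, report ordering and grid iteration are all
  deterministic; the only random number generators live in the synthetic
  module and are seeded explicitly.
- Problem sizes in the shipped tests and the acceptance script are
  desk-scale by design: 10–60 atom complexes, 20–200 frame ensembles,
  which exercise every code path of the ensemble scorer while keeping the
  whole suite in the seconds range.

## Known limitations

- Absolute ΔG values from the engine are not comparable to numbers
  produced by other GB parameterizations; only relative trends are.
- The published decomposition tables packaged as fixtures contain one
  internally inconsistent row (R18K: components sum to −58.23 vs a
  printed total of −59.32, a 1.09 kcal/mol residual; its ΔΔG column is
  consistent with the printed total). The fixtures are shipped verbatim;
  the consistency check reports the violation rather than repairing the
  data, and the corresponding acceptance test fails on that row by
  design.
- No angular hydrogen-bond term, no salt-bridge classification, no
  entropy estimate, no periodic boundary handling (solute-only frames are
  assumed), and no Michaelis–Menten fitting from raw progress curves.
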