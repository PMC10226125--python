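# Methods

## Scope and model

`pbsakit` rescoring operates on *end-state* (single-trajectory) decomposed
energy terms. For a protein P, ligand L and complex PL extracted from the same
frames, the binding free energy is modelled as

    ΔG_bind = ΔE_MM + ΔG_solv − TΔS
    ΔE_MM   = ΔE_vdW + ΔE_ele            (bonded terms cancel in one trajectory)
    ΔG_solv = ΔG_PB + ΔG_np

with Δx = ⟨x_PL − x_P − x_L⟩ over frames. The polar solvation term ΔG_PB is an
*input* (this package does not solve the Poisson–Boltzmann equation), and −TΔS
is zero except for the rotatable-bond surrogate in the empirical regimes.

### Nonpolar solvation regimes

| regime        | ΔG_np                                   | free coefficients |
|---------------|------------------------------------------|-------------------|
| `sasa_only`   | γ·ΔSASA + b                              | γ, b              |
| `sav_only`    | γ·ΔSAV + b                               | γ, b              |
| `sav_disp`    | γ·ΔSAV + b + ΔE_disp (disp coeff ≡ 1)    | γ, b              |
| `spt`         | γ·ΔSASA + p·ΔSAV + b                     | γ, p, b           |

The scaled-particle-theory (SPT) form carries both an area and a volume term
because cavity free energies cross over from volume-dominated (small cavities)
to area-dominated (large cavities). When the dispersion energy is exactly
linear in the volume, ΔE_disp = c₁·ΔSAV + c₀, the two-term cavity–dispersion
model collapses algebraically onto SPT with coefficients (0, γ+c₁, b+c₀) — an
identity the test suite asserts to 1e-10.

### Empirical and ML-substituted regimes

* `pbsa_e`: ΔG = α₁·ΔE_vdW + α₂·(ΔE_ele/ε_ele + ΔG_PB/ε_pb) + α₃·γ·ΔSASA +
  α₄·N_rot, with γ fixed at 0.0072 kcal·mol⁻¹·Å⁻² and N_rot the ligand's
  rotatable-bond count standing in for conformational entropy. The shared α₂
  reflects that both terms are electrostatic and scale together with the
  interior dielectric.
* `pbsa_ex`: every decomposed term gets its own α (five coefficients).
* `ani_*`: a machine-learned single-point energy difference
  ΔE_sp = ⟨E(PL) − E(P) − E(L)⟩, evaluated on identical geometries (no
  relaxation), replaces the gas-phase MM terms with a scale factor `a`:
  ΔG = a·ΔE_sp + ΔG_PB/ε_pb + ΔG_np. The backend is abstracted behind the
  `EnergyProvider` contract (deterministic, permutation- and rigid-motion-
  invariant); the bundled mock providers are closed-form pairwise potentials
  whose complex-minus-fragments difference is exactly the cross-fragment pair
  sum, which gives the tests an independent brute-force oracle.

### Two-valued interior dielectric

The solute (interior) dielectric constant appears in two places, the P–L
Coulomb term and the PB polar-solvation term, and the energy is inversely
proportional to it in both. `pbsakit` keeps the two values independent,
(ε_ele, ε_pb): a buried neutral ligand sees a nearly vacuum-like pocket
(ε_ele ≈ 1) while the solvent-exposed surface that dominates the PB term may
need a larger ε_pb. Rescaling is algebraic division of terms computed at
ε_int = 1 (`ΔE_ele/ε_ele`, `ΔG_PB/ε_pb`). This is exact for the Coulomb term
and an approximation for PB (a re-solve would redistribute the reaction
field); it is the approximation the rescoring workflow is built on, and it
makes grid scans over (ε_ele, ε_pb) cheap. At ε_ele = ε_pb the scheme reduces
exactly to the classical single-valued rescaling (asserted to 1e-12).

## Monte-Carlo surface and volume estimators

A probe sphere of radius `r_p` (default 1.4 Å, water; the radii table defaults
to the Bondi set, both swappable) defines three geometric observables for a
union of atomic vdW spheres inside an axis-aligned sampling cell:

* **ASA** — area of the boundary of the union of probe-inflated spheres
  (radius r_i + r_p). Estimated by per-atom stratified sampling: each atom's
  inflated sphere gets an equal share of `n_samples` uniform surface points; a
  point is accessible iff outside every other inflated sphere;
  area = Σ_i 4π(r_i+r_p)²·(accessible fraction). The standard error combines
  per-atom binomial variances.
* **PCAV molecular volume** — cell volume minus the volume available to the
  probe *centre* (points ≥ r_i+r_p from every centre), by uniform cell
  sampling. Subtracting the pore volume from the cell volume removes the cell
  dependence, which the tests verify across cell sizes.
* **POAV molecular volume** — the same subtraction with the probe-*occupiable*
  volume: points outside every vdW sphere and within r_p of some
  probe-centred-accessible location.

The POAV membership test is evaluated in closed form: the nearest accessible
point to a sample x lies on the boundary of the inflated-sphere union, which
stratifies into faces (single sphere surfaces), edges (pairwise intersection
circles) and vertices (triple intersections). The nearest candidate on each
stratum is analytic (radial projection; nearest point on the intersection
circle; the precomputed accessible triple-intersection vertices), so the test
is exact up to a 1e-9 boundary-classification slack. No reachability or
percolation analysis is performed: interior voids count as pore in both
definitions, consistent with the subtraction construction.

The three volume indicators are evaluated on the *same* sample points and are
nested (probe-centred ⊆ probe-occupiable ⊆ outside-vdW), so the ordering
vdW ≤ POAV ≤ PCAV molecular volume holds deterministically, not just in
expectation. As r_p → 0 all three collapse onto the vdW volume and ASA onto
the vdW surface area.

**Randomness.** All sampling uses the counter-based Philox generator with
substreams keyed by (seed, stream, atom index), so results are bit-reproducible
for a fixed seed and independent of atom iteration order. Sampling is done in
cell-local coordinates, making estimates invariant (to ~1e-9 relative,
limited by float rounding of the shifted coordinates) under rigid translation
of structure plus cell.

**Grid oracle.** `grid_oracle` recomputes all quantities deterministically:
voxel counting on a lattice (default 0.05 Å) for the volumes, with the
probe-occupiable region obtained as outside-vdW voxels whose Euclidean
distance transform to the probe-centred-accessible voxel set is ≤ r_p, and a
fixed Fibonacci-spiral quadrature for the area. Because the EDT measures
distance to accessible voxel *centres* — which sit on average half a voxel
inside the continuum region — the threshold carries a +0.5·resolution
correction; against the single-sphere closed form this cuts the POAV error
from +0.93% to +0.20% at 0.05 Å. The oracle exists for validation only; its
cost grows as (cell/resolution)³.

## Fitting and evaluation

Every regime's prediction is affine in its coefficients (asserted by finite
differences in the tests), so fitting is ordinary least squares of
ΔG_pred on ΔG_exp with pinned coefficients folded into the offset.
Rank-deficient designs (e.g. ΔSASA ≡ ΔSAV) raise a singular-design error
naming the collinear columns. Coefficient standard errors come from the
closed-form OLS covariance; per-frame standard errors of the input deltas are
carried through and reported but never used to weight the fit. The objective
is SSE by default; an alternative `pearson` objective rescales the SSE
solution by a 1-D search over a common coefficient scale maximising Pearson R
(the two coincide whenever the regime has no fixed offset terms).

Dielectric grid scans evaluate the metric suite on every (ε_ele, ε_pb) pair
(or the diagonal for the single-valued variant), either reusing fixed
coefficients (pure rescaling) or refitting the free coefficients per pair; the
best pair is the Pearson-R argmax with ties broken toward the smaller pair.

Metrics: Pearson and Spearman correlations (average ranks for ties); the
predictive index PI = Σ w_ij c_ij / Σ w_ij over pairs, weighted by the
experimental affinity gap, where c_ij = ±1 by the sign concordance of the
experimental and predicted differences and 0 for a tied prediction (larger
predicted ΔG with larger experimental ΔG counts +1; ties in experimental
values carry zero weight); and the MUE family — raw MUE, MUEtr after removing
the mean signed error, and MUEsc after least-squares affine mapping of the
predictions onto experiment. PI, the correlations and MUEsc are invariant
under positive-affine transforms of the predictions; MUEtr under shifts only.

## Synthetic data

The generators define the study conditions for all statistical tests:

* `gen_cluster`: connected random sphere clusters (each sphere overlaps an
  earlier one at a centre distance of 0.75× the radius sum by default, radii
  from the element table over C/N/O/S, 1.52–1.80 Å), giving structures with
  grooves and pockets but oracle-checkable geometry.
* `gen_study`: 54 complexes by default, mirroring a mid-sized end-state
  benchmark. Term differences are normal draws — ΔE_vdW ~ N(−45, 10),
  ΔE_ele ~ N(−25, 12), ΔG_PB ~ N(+45, 15), ΔE_disp ~ N(−30, 8),
  ΔE_sp ~ N(−60, 15) kcal/mol, ΔSASA ~ N(−750, 140) Å² with
  ΔSAV = ΔSASA + N(0, 90) Å³ so that area and volume differences are strongly
  correlated but not collinear, as they are in real complexes where both fall
  in the −500…−1000 range; N_rot uniform on 0…15. ΔG_exp is the chosen
  regime's formula at the true coefficients (default the SPT set γ=0.1394,
  p=0.0163, b=0) and true dielectric pair, plus Gaussian noise (default
  σ = 1 kcal/mol, the scale of a careful experimental binding assay).
  Per-frame tables decompose each delta into plausible P/L/PL species
  baselines with *exactly zero-sum* frame jitter, so frame averaging recovers
  the drawn deltas at machine precision and averaging tests are exact rather
  than statistical.

What the generator does **not** emulate: real force-field correlations between
terms, frame-to-frame autocorrelation, charged ligands (where the algebraic
dielectric rescaling is least defensible), conformational strain, or any
structural realism beyond overlapping spheres. Passing tests therefore
demonstrate the correctness of the estimators, fitting machinery and geometry
sampling — not the physical accuracy of end-state rescoring on real
protein–ligand systems.

## Numerical choices and problem sizes

* Geometry tests compare MC estimates (4×10⁵ cell samples, 10⁵ surface
  samples) against the 0.05 Å grid oracle on clusters of 5–20 spheres inside
  cells padded by 2 Å + r_p; tolerance max(3·stderr, 1%).
* Coefficient recovery uses n = 54 complexes: exact (1e-8) at zero noise, and
  bias < 2 Monte-Carlo standard errors over replicated fits at σ = 1 kcal/mol.
* Dielectric-scan recovery plants the truth at (ε_ele, ε_pb) = (1, 4) on an
  integer 1–10 grid; the two-valued scan must recover it with R = 1 and the
  diagonal-constrained scan must be strictly worse.
* Algebraic identities (decomposition audit, regime reductions, dispersion
  collapse, diagonal consistency) are asserted at 1e-10…1e-12.
* Degenerate inputs raise typed errors rather than returning NaN: zero
  experimental variance (PI), zero prediction variance (MUEsc, correlations),
  rank-deficient designs, cells too small for the inflated spheres, lattices
  too coarse to resolve the smallest atom (< 10 voxels).

## Known limitations

* ΔG_PB is consumed, never computed; the dielectric machinery is an algebraic
  rescaling of ε_int = 1 inputs.
* The PB/GB re-solve, MD sampling, charge derivation and real ML-potential
  inference all live upstream; `torchani`-style backends can be plugged in via
  `EnergyProvider` but are not bundled.
* Pore volumes include interior voids; for structures with sealed cavities
  PCAV/POAV molecular volumes exceed the solvent-visible molecular volume.
* The empirical regimes assume neutral ligands; strongly charged systems need
  larger, possibly residue-dependent dielectric treatments outside this
  package's scope.
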