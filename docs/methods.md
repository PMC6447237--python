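# Methods

## Scope and model

`saxsbm` implements scattering-guided native structure-based (Gō-type)
molecular dynamics: an all-atom SBM potential V_SB whose parameters are
read off a native structure, extended by a pseudo-energy
V_XS = (k_χ/2)·χ² that penalizes disagreement between the simulated and
target SAXS *difference* curves. Difference data are used because they
isolate the structural change and cancel systematic and solvation-layer
contributions, which is what justifies the deliberately simple
solvation treatment below.

### Structure model

Structures are heavy-atom only; hydrogens and solvent are implicit.
All internal lengths are nm (PDB Å converted on I/O). For NMR entries
the first model is used unless another is requested; alternate
locations resolve to the highest occupancy with ties broken toward
altloc 'A'; HETATM records (waters, ligands, ions) are dropped, so
liganded crystal forms are treated unliganded.

### Force field (reduced units)

Energy unit ε, unit masses, unit radii. Terms and constants:

| term | form | constant | default |
|---|---|---|---|
| bond | K_b(r−r₀)² | K_b | 20 000 ε/nm² |
| angle | K_a(ϑ−ϑ₀)² | K_a | 40 ε/rad² |
| improper | K_i(χ−χ₀)² | K_i | 40 ε/rad² |
| proper | K_d[(1−cosΔϕ)+½(1−cos3Δϕ)] | K_d | from normalization |
| contact | K_c[(σ⁰/r)¹²−2(σ⁰/r)⁶] | K_c | from normalization |
| non-native | K_nc(σ̃/r)¹² | K_nc, σ̃ | 0.01 ε, 0.25 nm |

No extra ½ factors on the harmonic terms. The angle/improper constants
are interpreted per squared *radian* (the conventional choice for
all-atom SBMs); a config switch exposes the literal per-degree² reading
for comparison. The non-native excluded-volume radius σ̃ = 0.25 nm is a
package choice of the order of a heavy-atom van der Waals contact.

**Topology construction.** Bonds come from amino-acid templates plus
peptide bonds (chain breaks — C–N beyond 0.2 nm — are an error naming
the gap); angles from all bonded triplets; one proper dihedral per
rotatable non-ring central bond (lowest-index flanking atoms);
impropers at every centre with ≥3 heavy neighbours, which covers sp²
planarity and Cα chirality with native reference values. Native
contacts use a simple heavy-atom cutoff map (0.45 nm default,
configurable) between residues separated by more than three sequence
positions. Shadow-map contact algorithms are intentionally out of
scope; the contact builder is the natural extension point.

**Normalization.** K_c and K_d are uniform and scaled so that
ΣK_c + ΣK_d = n_atoms with a 2:1 contact:dihedral split (configurable).
If one class is empty (tiny peptides have no contacts), the other
receives the full budget so the sum rule still holds. This
parameterization sets the folding temperature of the model near one ε
of thermal energy, i.e. ~120 reduced temperature units with the k_B
convention below. The precise backbone/side-chain partition used by
the original eSBM tooling is not public; the uniform split is this
package's documented stand-in.

**Exclusions.** Pairs within three bonds, plus all native contact
pairs, are excluded from the non-native repulsion.

### Scattering model

One scatterer per residue at its heavy-atom centre of mass (unit
masses ⇒ centroid), matching the low resolution of solution scattering
and keeping the O(N²) Debye sum cheap. The default form factor is a
single-Gaussian contrast model per residue type:
f(q) = c·exp(−(qR)²/2) with c = (residue electron count) − ρ_s·V
(ρ_s = 334 e/nm³, V a published mean residue volume) and R the radius
of gyration of the equivalent sphere. Published multi-Gaussian residue
tables can be plugged in via the provider interface; note that absolute
intensity scales — and therefore useful k_χ magnitudes — are not
transferable between parameterizations. There is no hydration-shell
term anywhere: difference-curve guiding is robust to solvation detail,
and the model caps q at 5 nm⁻¹ where shape information dominates.

Gradients ∂I/∂r are analytic:
∂I(q)/∂r_i = Σ_{j≠i} 2fᵢfⱼ[cos(qr)−sinc(qr)]/r · r̂_ij, with the r→0
limit contributing zero. Site gradients map to atoms through the
centre-of-mass weights (chain rule).

### Bias

χ² = Σ_q [(ΔI_exp − α{I_calc − I_ref})/σ_q]². α is the fraction of the
sample undergoing the transition; with purely synthetic targets the
whole sample converts, so α = 1 by default. Weights from experimental
errors prefer difference-curve errors over reference errors:
σ_q = σ_Δ/|ΔI_exp| + 1 (fallback σ_ref/|I_ref| + 1), with a guard
δ = 10⁻⁶·max|ΔI| against zero crossings of the difference curve; both
algebraic readings of the weight formula sit behind a config switch,
and absent errors give σ_q ≡ 1 exactly. This form down-weights the
noisier wide-angle points. The bias is recomputed every integration
step by default (`bias_stride` trades accuracy for speed on large
systems).

**Noise model for synthetic data.** Clean intensities are blurred with
Gaussian noise of standard deviation √I per point; noisy differences
subtract the blurred curves, and their errors add as the sum of the two
absolute standard deviations.

### Dynamics

Langevin dynamics with a BAOAB splitting: with friction γ = 0 the
scheme reduces exactly to velocity Verlet, which is what the
energy-conservation checks exercise. k_B = 0.00831451 ε per reduced
temperature unit, so printed temperatures (50–110 for guided runs,
folding ≈ 120) carry over numerically. Defaults dt = 5·10⁻⁴ reduced
time, γ = 1 reduced⁻¹, Maxwell–Boltzmann initial velocities under the
run seed; all exposed in the configuration. Simulated time is
steps × dt in arbitrary reduced units. Integrator blow-up (the failure
mode of excessive k_χ) raises a structured error carrying the step and
the last stable frame; the grid-search driver records such cells as
undefined instead of aborting.

### Analysis

Cα-only Kabsch RMSD (proper rotations, residual measured after applying
the optimal rotation) against both the initial and the target
structure, using the shared-residue intersection when coverages differ.
Reports include the minimum target RMSD and its frame, the bias-energy
minimum and average, average χ², the Pearson correlation between V_XS
and target RMSD, the earliest time below a 0.2 nm target RMSD
(reported in reduced time — wall-clock timing is hardware-bound and out
of scope), end-to-end Cα distances, radius of gyration, and
asphericity A = [(λ₁−λ₂)²+(λ₂−λ₃)²+(λ₃−λ₁)²]/[2(λ₁+λ₂+λ₃)²] ∈ [0,1]
from the gyration-tensor eigenvalues (0 for spherical symmetry, 1 for a
rod; this normalization is fixed and documented here because more than
one convention exists). Averages span the full trajectory; a burn-in
flag can drop equilibration frames.

## Synthetic fixtures: what they emulate and what they do not

`build_ideal_helix` produces a deterministic all-heavy-atom α-helix
(φ = −57°, ψ = −47°, ω = 180°, standard peptide geometry; side chains
grown in extended rotamers with approximately tetrahedral branching and
cis-curled rings). It emulates the "elongated" member of a two-state
pair. `build_two_state_polymer` produces a single-CA bead chain (bond
0.38 nm) in a hairpin conformation (two-bond turn, arm separation
~0.66 nm, small seeded out-of-plane jitter so no native dihedral is
degenerate) and an exactly straight extended conformation.

These fixtures capture the essential physics probed here — a funneled
single-basin force field competing with a scattering bias toward a
distinct global shape — but not side-chain packing frustration,
secondary-structure rearrangement, or realistic contact-map density.
Passing the transition-recovery tests therefore demonstrates the
machinery (gradients, bias balance, integrator) rather than predictive
accuracy on real proteins, which the PDB-based checks cover when
network access to RCSB is available.

## Problem sizes and numerical choices

Test and acceptance runs use 4–16-bead polymers and 7–21-residue
helices with 4·10³–10⁵ steps, sizes at which the exact O(N²) Debye
double sum per step is cheap; larger systems should raise
`bias_stride`. Finite-difference force checks use central differences
(step 10⁻⁶ nm) and pass at relative error <10⁻⁶ (SBM terms) and <10⁻⁵
(bias). Angle gradients guard sin ϑ ≥ 10⁻⁸; dihedrals with degenerate
(collinear) flanking geometry are skipped at topology build time, which
is what makes the exactly straight polymer a valid scattering target
while the jittered hairpin serves as the dynamical native state.
Coincident atoms in a repulsive pair raise a singularity error rather
than returning infinities.

## Known limitations

- Cutoff contact map only; no shadow map, no multi-basin (multi-Gō)
  potentials.
- Single-Gaussian residue form factors; no Cromer–Mann atomic factors,
  no explicit hydration layer, no wide-angle (q > 5 nm⁻¹) modeling.
- α is fixed, not fitted; no ensemble reweighting.
- Bias weights k_χ are not transferable across systems or form-factor
  scales and must be re-tuned by grid search per system.
- Transitions that barely change the molecular shape (e.g. subdomain
  rotations around a helix bundle) are not expected to converge: the
  difference curve does not constrain them, a known failure mode of
  SAXS-guided refinement generally.
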