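# Methods

This note documents the models implemented in `mmsie`, the parameter
defaults and why they have those values, the numerical choices that affect
results, what the synthetic-data generator does and does not emulate, and
the package's known limitations.

## Scope and conventions

`mmsie` is a post-processor: it consumes an equilibrated trajectory of a
receptor–ligand complex (multi-model PDB or plain text) plus a topology
sidecar carrying the per-atom force-field quantities PDB cannot hold
(partial charge, Lennard-Jones σ/ε, intrinsic Born radius and descreening
scale, mass, donor/acceptor flags, harmonic bonds).  It never runs
dynamics.  Units are Å, ps, kcal/mol, elementary charge and amu
everywhere; atom indices are 0-based internally and 1-based only in files.
The Coulomb constant is fixed at k_e = 332.0637 kcal mol⁻¹ Å e⁻², the
AMBER convention, for consistency with the force-field family the input
parameters are expected to come from.

Snapshot windows are half-open, (start, end], sampled at start + k·stride
with k ≥ 1: "N snapshots from the last T ns at interval s" then comes out
exactly (200 frames at 100 ps over a 20-ns window; 50 at 400 ps), and a
stride larger than the window is an empty selection and a hard error.

## End-point binding free energies

Both estimators use the single-trajectory convention: complex, receptor
and ligand states are all taken from the same complex frame, so
intramolecular bonded terms cancel and only intermolecular interaction
terms and solvation differences remain.  The MM-GBSA sum is

ΔG = ΔE_ele + ΔE_vdw + ΔG_pol + ΔG_nonpol − TΔS

with ΔE_ele and ΔE_vdw the receptor–ligand Coulomb (dielectric 1) and
12-6 Lennard-Jones (Lorentz–Berthelot combination) cross energies, no
non-bonded cutoff (a cutoff belongs to the dynamics engine, not to
end-point rescoring; a flag exists but defaults off), ΔG_nonpol =
γ·ΔSASA + β with γ = 0.0072 kcal mol⁻¹ Å⁻² and β = 0, and the entropy
penalty stored as the signed quantity −TΔS (positive when binding is
penalized) and simply added.  The per-component dispersion quoted next to
each mean is the sample standard deviation over snapshots,
√(Σ(xᵢ−x̄)²/(N−1)) — the statistic end-point tables conventionally print
under the label "standard error"; it is frozen as such and is not the
standard error of the mean.

The SIE score is the empirical affine combination

ΔG = α·[E_c(D_in) + ΔG^R + E_vdW + γ·ΔMSA(ρ)] + C

with the published coefficient set α = 0.1048, D_in = 2.25, ρ = 1.1,
γ = 0.0129 kcal mol⁻¹ Å⁻², C = −2.89 kcal/mol as frozen defaults.  E_c is
the intermolecular Coulomb energy at the interior dielectric D_in.  ΔG^R,
the reaction-field change on binding, is computed with the
generalized-Born machinery below at interior dielectric D_in.  This is a
deliberate surrogate for a boundary-element Poisson solver: GB is an
analytic approximation to the same reaction field, and the package
documents it as such rather than claiming Poisson accuracy.  The
molecular-surface term uses the accessible area with all atomic radii
scaled by ρ and probe radius 0 — a scaled-radius approximation to the
molecular (Connolly) surface; a `surface-kind` switch is reserved should
an analytic surface engine be added.

## Generalized Born (OBC)

Effective Born radii come from the pairwise descreening integral of
Hawkins–Cramer–Truhlar with the tanh rescaling of Onufriev, Bashford and
Case:

R_i⁻¹ = ρ̃_i⁻¹ − tanh(αψ − βψ² + γψ³)/ρ_i,  ψ = I_i·ρ̃_i,

where ρ̃_i = ρ_i − offset (offset 0.09 Å) and I_i sums the analytic
pairwise integral of r⁻⁴ over each neighbour's scaled sphere, with the
interior correction when atom i's centre lies inside a neighbour sphere.
The shape constants default to (α, β, γ) = (0.8, 0, 2.909125) — the OBC-I
(igb=2) set; the OBC-II set (1.0, 0.8, 4.85) is selectable by name
(`GBModelParams.variant("obc2")`).  An isolated atom recovers R = ρ − offset
exactly.  The polar energy is the usual cross-term sum with
f_GB = √(r² + R_iR_j·exp(−r²/4R_iR_j)) and prefactor
−k_e(1/ε_in − 1/ε_out)/2 including self-terms, so a single ion reproduces
the Born formula exactly.  ΔG_pol of binding recomputes radii for each
state (complex, receptor alone, ligand alone) from the same coordinates.
Exterior dielectric defaults to 78.5 (water); interior to 1.0 for MM-GBSA
and D_in = 2.25 when serving the SIE reaction field.

## Surface areas

SASA uses Shrake–Rupley sphere sampling with a deterministic golden-spiral
point set (default 960 points) — no RNG, so areas are bit-reproducible.
Because a fixed lab-frame point set is not rotation-invariant, sampling
happens in a molecule-fixed canonical frame (weighted centroid + principal
axes, signs fixed by the third moment); rigid motions of the input then
change nothing, to 1e-9.  The residual orientation-independent
discretization error is ~0.1% of a sphere's area at 960 points; binding
differences between separated partners are therefore zero only to that
resolution (~0.01–0.05 Å², i.e. < 1e-3 kcal/mol through either γ).

## Normal-mode entropy

For toy systems whose analysis potential is intra-selection Coulomb +
Lennard-Jones (1-2 bonded pairs excluded) + harmonic bonds
E = ½k(r−r₀)², the structure is first driven to a local minimum
(L-BFGS with analytic gradients, Newton-polished toward gradient norm
1e-8 kcal mol⁻¹ Å⁻¹), the Hessian is built by central differences of the
analytic gradient (step 1e-4 Å, symmetry enforced after checking the
asymmetry is < 1e-6 of the largest element), mass-weighted, and the
rigid-body subspace — an SVD basis of the translation and rotation
generators, which degrades gracefully to 5 modes for linear molecules —
is projected out.  Remaining negative eigenvalues beyond round-off are a
hard error reporting the count (the structure was not a minimum).
Frequencies follow from ω = √λ with λ in kcal mol⁻¹ Å⁻² amu⁻¹ converted
via CODATA constants; the harmonic-oscillator vibrational entropy at
temperature T (default 300 K) is S = R·Σ[x/(eˣ−1) − ln(1−e⁻ˣ)],
x = hν/k_BT, and the binding quantity is −T·[S(complex) − S(receptor) −
S(ligand)].  Translational/rotational entropy is not included: the
package computes the vibrational term that normal-mode analysis
contributes; for the toy systems in scope the binding difference is
dominated by it.

## Structural dynamics

Superposition is the Kabsch algorithm (SVD with the determinant
correction, so reflections are excluded), mass-unweighted — for Cα-only
analyses mass weighting is a constant factor.  RMSD uses separate fit and
measure selections ("backbone" = N, Cα, C, O).  RMSF, the
cross-correlation matrix and covariance PCA use one fit-to-mean
iteration: fit all frames to frame 1, compute the mean structure, refit
to the mean.  One iteration is the standard compromise; further
iterations change results below sampling noise.

The fit uses its own `fit_selection` (default: all atoms), distinct from
the analysis selection.  This matters: superposition removes six
rigid-body degrees of freedom, and if the fitted atoms are exactly the
correlated ones, genuine common-mode motion is absorbed into the fit and
positive designed correlations invert (measured on the synthetic suite:
a designed +0.8 inter-block correlation is recovered as −0.79 when
fitting on the signal atoms, +0.80 when fitting on low-variance anchor
atoms).  Real analyses should fit on a stable core — as is standard
practice — and the parameter-recovery tests pin the fit with
small-variance anchors.

The DCCM is c_ij = ⟨Δr_i·Δr_j⟩/(⟨Δr_i²⟩⟨Δr_j²⟩)^½ over the fitted
displacement vectors; it is symmetric with unit diagonal and entries in
[−1, 1] by construction, and atoms with zero variance get off-diagonal 0
(diagonal 1) with a warning rather than NaN.  PCA diagonalizes the
3N×3N coordinate covariance; eigenvalues are clipped at 0 (the matrix is
positive semidefinite up to round-off) and the cumulative fraction of the
leading k modes summarizes how concerted the motion is.

## Hydrogen bonds

A donor–H…acceptor triple qualifies in a frame iff the heavy-atom
donor–acceptor distance is strictly < 3.5 Å and the angle at the hydrogen
(subtended by the donor heavy atom and the acceptor) is strictly > 120°;
both thresholds are configurable and both inequalities are strict, so
boundary geometries do not qualify.  The angle criterion is stated in
the source convention "acceptor…H–donor"; computed at the hydrogen the
two readings coincide.  Donor/acceptor roles come from topology flags and
a donor's hydrogens from the bond list (element-only inference is
ambiguous for ligands).  Occupancy is 100 × qualifying/total frames;
geometry means are over qualifying frames only.

## Synthetic data: what it does and does not show

The generator builds deterministic toy complexes (byte-identical files
for a fixed spec) with hand-computable reference energies — a +1/−1 pair
at 3.320637 Å gives exactly −100 kcal/mol Coulomb — and optional designed
hydrogen-bond triples placed at exact distance/angle targets.
Correlated trajectories are zero-mean Gaussian displacements about a
reference with a designed per-axis covariance √v·C·√v; the block
correlation matrix is checked for positive semidefiniteness before
sampling (hard error naming the offending eigenvalue).  Gaussian
sampling is the right ground truth for DCCM/RMSF/PCA — those statistics
depend only on the displacement distribution — but it is not dynamics:
there is no kinetics, no anharmonicity, no solvent, and the toy
force-field parameters are not a parameterization of any real ligand.
Passing the recovery suite therefore demonstrates the estimators are
correct on their own model assumptions, not that a 60-ns explicit-solvent
trajectory of a real complex would be reproduced; published MD-derived
numbers (mean RMSDs, PC fractions, per-residue energies, occupancies)
depend on trajectories that are not redistributable, so the packaged
component tables are carried as fixtures and only the component→total
combinations are recomputed.

Problem sizes in the default suite are chosen for tight sampling bounds
at interactive runtimes: 24-atom complexes, 2000-frame trajectories for
variance recovery (5% tolerance), 5000 frames for correlation recovery
(±0.05) and spectrum shape (±5%), 960–4000 sphere points for areas
(1–2% analytic tolerances).

## Known limitations

* No Poisson–Boltzmann solver: ΔG^R is the GB surrogate described above;
  no salt dependence.
* No Connolly/analytic molecular surface; ΔMSA is the scaled-radius
  accessible-surface approximation.
* Normal-mode entropy covers the vibrational term only and requires the
  toy analysis potential (topology-supplied bonds); it is not a
  general-purpose force-field normal-mode engine.
* Residue decomposition assigns GB cross-terms 50/50 between the two
  atoms' residues (the common convention); only the ele+vdw parts are
  exactly conservative against the total interaction energy.
* No periodic boundary conditions, PME or bonded terms: analyses operate
  on isolated complexes, as end-point methods assume.
* AMBER prmtop/inpcrd and binary trajectory formats (DCD/XTC) are out of
  scope; inputs arrive as PDB/plain text plus the YAML sidecar.
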