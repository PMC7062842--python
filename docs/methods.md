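# Methods

This note records the models implemented in `diffusekit`, their assumptions,
the parameters that matter, and the numerical choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Conventions and units

- Coordinates are Cartesian angstroms internally; fractional coordinates
  appear only at I/O. The scattering vector is `s = h a* + k b* + l c*`
  with `a*·a = 1`, so `|s| = 1/d` in Å⁻¹. Quantities conventionally quoted
  against `q` use `q = 2πs` at presentation only.
- Spring constants γ are in energy/Å². Because the models are classical and
  harmonic, the temperature enters only through the product kT·γ⁻¹; the
  package folds kT into the spring-constant scale (`kT = 1` by default, γ in
  kT/Å²), which is the natural convention when constants are refined against
  absolute intensities. Sound-speed slopes dω/dq then carry the natural unit
  `sqrt(kT/amu)`; `frequency_unit_km_per_s(T)` converts to km/s for a
  physical temperature.
- Diffuse intensities are electron units (Iₑ) per unit cell once absolutely
  scaled.

## Crystal and networks

Structures are read with gemmi (P1 only; the target crystal form has one
molecule per cell). Alternate conformers are collapsed to occupancy-weighted
mean positions; hydrogens are excluded from all contact detection (the
all-atom internal network is defined over non-H atoms, and the same rule is
applied to lattice-contact detection because hydrogen placement is ambiguous
at typical resolutions).

Two spring types act on the relative displacement du of the end-point atoms:
Gaussian, `V = ½γ|du|²`, and directional, `V = ½γ(du·r̂)²`. Each physical
spring is stored once in a canonical orientation; the edge `(j, j′, l)` and
its lattice image `(j′, j, −l)` are the same object, so a P1 crystal with
one molecule per cell has exactly half as many unique springs as directed
contacts.

- The **lattice network** links the Cα atoms of every residue pair (central
  molecule, one of the 26 neighbor cells) with any non-H atom pair within a
  cutoff (default 4 Å), and treats the whole molecule as one rigid body.
- The **internal network** joins non-H atoms of different residues within
  the same cutoff, inside the molecule and across the 26 neighbors, all
  springs directional; each residue is a rigid body. Spring constants are
  the geometric mean `γ_jj′ = sqrt(g_i g_i′)` of per-residue couplings.

## Rigid-body lattice dynamics

Each rigid group carries 3 translations plus infinitesimal rotations about
its center of mass along the principal inertia axes (TLS/RTB convention,
rows `[I₃ | axis×(r−com)]`). Groups with rank-deficient inertia (single
atoms, collinear atoms) keep fewer rotational coordinates, which keeps the
mass matrix invertible — a point-molecule toy is therefore purely acoustic.
Masses come from element weights; inertia uses non-H atoms, consistent with
network building.

The pair Hessian `K = γ_gauss I + γ_dir r̂r̂ᵀ` is projected into group
coordinates to give force-constant blocks Φ(l); the dynamical matrix
`D(k) = M^{-1/2} Σ_l Φ(l) e^{2πi k·l} M^{-1/2}` is Hermitian and satisfies
the acoustic sum rule by construction. Eigenvalues below `1e-8` of the
maximum count as zero modes; this cleanly separates the three acoustic
modes at k = 0 for every network tested.

Covariances are classical equipartition accumulated on the Born/von-Karman
wavevector grid of the chosen supercell:
`C(l′) = (kT/N_k) Σ_k e^{2πik·l′} M^{-1/2} D(k)⁺ M^{-1/2}`, with the
pseudo-inverse dropping zero modes. Atomic ADPs are `U_j = A_j C(0) A_jᵀ`.
The supercell defaults to the map subdivisions so the wavevector mesh and
the voxel grid coincide.

## One-phonon scattering

At a voxel `s = s₀ + k`,

    I₁(s) = kT Σ_m |F₁(s,m)|² / ω_m(k)²,
    F₁ = Σ_j f_j(s) T_j(s) (2πi s·u_j^m) e^{2πi s·r_j},

with `u_j^m = A_j M^{-1/2} e_m` the rigid-body mode displacement. This is
the exact linearization of the pair-sum diffuse intensity in the phonon
covariances; the test suite verifies it against a Guinier-equation estimate
on a harmonic ensemble sampled from an independently built supercell
Hessian. Bragg voxels (k = 0) are excluded. Acoustic modes make
`I₁ ∝ |k|⁻²` near the nodes; soft optical (librational) branches provide
the nonzero floor mid-way between nodes — the "cloudy" component.

Form factors are the standard four-Gaussian-plus-constant parameterization
(gemmi's IT92 table). The FFT structure-factor path splats atoms as
real-space Gaussians with an anti-aliasing B-sharpening chosen so the
aliased tail at the grid Nyquist is below 1e-7; the sharpening is exact for
Gaussian form factors and the path agrees with the direct sum to 1e-4.

Bulk solvent follows Babinet's principle: excluded-solvent voxels are
partitioned among the modeled atoms by proximity (minimum image), each
partition becomes an anisotropic Gaussian pseudo-atom with the partition's
first and second moments, and `(k_solv, B_solv)` minimize
`Σ(F_obs − |F_calc + k_solv e^{−B_solv s²/4} F_solv|)²`. Pseudo-atoms join
the rigid group of their nearest protein atom and participate in the
one-phonon sums.

## Halo analysis and spring refinement

Halos are blocks of voxels whose nearest node is a given reflection; the
most intense halos are ranked by integrated block intensity (peak-value
ranking is the other defensible choice; integration is more robust to
single-voxel noise). Power-law exponents are least-squares log–log slopes
with the two sides of the node averaged; only the inner half of the profile
is used to avoid contamination by neighboring halos. The shape fit
`1/I = (q−q₀)ᵀG(q−q₀)` is linear in the six components of G; the anisotropy
is `a = G⊥/G∥ − 1` with `G∥ = q̂₀ᵀGq̂₀`.

Refinement minimizes the reduced χ² over halo voxels with the per-halo
offsets `b_n` profiled out in closed form (weighted mean residual per halo)
at every objective evaluation, so χ² is exactly invariant to adding any
constant to one halo. Four stages: (1) one Gaussian constant; (2) one
Gaussian constant per interface, where an interface is the set of springs
sharing a neighbor translation ±l; (3) per-interface Gaussian/directional
mixture; (4) per-spring mixture. Each stage starts from the previous
solution; a stage that increases χ² is reverted. The optimizer is bounded
least squares on log-constants (positivity) with the mixture fraction bound
to [0, 1]; Debye-Waller factors are recomputed from the trial model's own
covariances when a supercell is supplied.

## Internal dynamics and projection

The rigid-residue Hessian is modified as `V := PᵀVP` with
`P = I − (A\A₀)(A₀\A)` (whole-molecule suppression) or the analogous form
with the 3n×6d per-domain basis (domain suppression). Matrix division is
least-squares (rank-revealing, relative tolerance 1e-10); P is checked
idempotent to 1e-8. The equations of motion are solved at the Γ point of a
single unit cell, with neighbor displacements identified with the central
cell's; suppressed directions become exact zero modes and drop out of the
generalized inversion. Coupling constants are refined on log g (bounded,
deterministic start g = 1) against the 9 tensor components per atom of the
residual ADPs `U_meas − U_latt`.

The directional correlation
`CC_jj′ = r̂ᵀ⟨u_j u_j′ᵀ⟩r̂ / sqrt((TrU_j/3)(TrU_j′/3))` exposes the
hinge-bending signature: in a two-lobe toy molecule whose lobes touch only
through a hinge residue, whole-molecule suppression leaves strong lobe-lobe
correlations while per-domain suppression removes them.

## Diffuse Patterson

The experimental route fills missing and Bragg voxels with the mean of
their 26-neighborhood (iterated until none remain inside the resolution
limit; an error is raised if more than half the voxels in the limit are
missing), subtracts the mean intensity per resolution shell (Δs = 0.02 Å⁻¹,
matching the CC binning), zeroes voxels beyond the resolution limit,
zero-pads to the requested real-space sampling, and applies a 3D FFT. The
forward transform carries the reciprocal voxel volume, so Patterson values
are e²/Å³ per unit cell.

The model route evaluates the pair sum

    I_D(s) = Σ_j f_j { Σ_{l′,j′} f_j′ e^{2πi s·(r_j − r_j′ − r_l′)} T_j T_j′ (T_cross − 1) }

over the reference cell and its 26 neighbors within a distance cutoff
(default 29 Å, slightly beyond the 25 Å analysis window to avoid truncation
artifacts), with `T_cross = exp(+4π² sᵀ⟨u_j u_j′ᵀ⟩ s)` from the model
covariances, then pushes the resulting map through the same shell-mean
subtraction and FFT. The effective factor splits additively into lattice
and internal parts, which makes Patterson(lattice) + Patterson(internal) =
Patterson(combined) exact under the independence assumption. Internal
motions are intramolecular: cross-cell internal covariances are set to zero
(independent molecules), while the lattice covariances carry the full
cross-cell structure. The two routes (pair sum with exact exponential cross
terms vs FFT of the mode-sum one-phonon map) agree within 5% in shell
standard deviation between 2 and 10 Å on the test lattice, which validates
both the covariance-to-T mapping and the FFT bookkeeping.

Reciprocal-space CC between Pattersons zeroes |r| < 2 Å and |r| > 25 Å,
truncates to ±1 cell per axis (2× reciprocal oversampling), inverse
transforms, and computes Pearson CC in shells of Δs = 0.04 Å⁻¹.

## Map processing

**Integration mask.** Per provisional voxel (reciprocal cell subdivided by
5), a histogram of photon counts per pixel is kept. For each neighborhood
(voxels within Euclidean distance 2), the weighted median of member voxel
rates — weighted by pixel multiplicity — defines a Poisson reference, and
the KL divergence of the pooled histogram from it scores the neighborhood
(the Poisson pmf is truncated at its 1−1e-9 quantile). Voxels are ranked by
the change Δ_KL their exclusion causes, masked progressively in ascending
order with neighbor updates but no re-sorting, halting at the first
Δ_KL ≥ 0. On planted data this removes ≥95% of Bragg-like voxels at ≤5%
diffuse cost. In a *perfect* Poisson null the literal algorithm still masks
the few chance-worst voxels (a few percent at desk-scale statistics, and
the effect does not vanish with more pixels per voxel): removing a
neighborhood's most deviant member almost always lowers its KL more than
the smaller-sample bias raises it. This is a property of the stated
algorithm, not of the implementation.

**Pixel corrections.** The virtual detector is a flat panel normal to the
beam with a chip tiling; corrections cover polarization, solid angle
(cos³2θ), sensor absorption efficiency, and air attenuation, and
backgrounds (crystal-translated-out exposures) are subtracted frame by
frame with Poisson error propagation. Real-detector metrology (parallax,
goniometer error) is out of scope.

**Scaling.** The model
`I_pred = a(x,y,φ) d(p) [b(φ) I_merge + c(s,φ)]` is refined by alternating
regularized linear block solves in the sequence {b, o, cb, o, c, a, d}
(o = 5σ outlier rejection), updating I_merge after every block. Second
derivatives regularize a, b, c; c is clipped non-negative and pulled to
zero; d is pulled to one where unconstrained. The gauge is fixed by
normalizing mean(b) = 1. Only the product a·b·d (and c) is observable — the
φ-dependence of a is gauge-shared with b — so recovery is assessed on the
total gain. Grids default to the full-scale sizes (9×9 detector, 26 φ
points per 50° wedge, 100 s points to 0.9132 Å⁻¹, 960 chips) but are
configurable; tests use smaller grids matched to their redundancy.

**Merging** is inverse-variance weighted per fine-grid voxel with Friedel
averaging; the half-dataset split assigns shuffled observations greedily to
the lighter half by accumulated inverse variance (seeded), giving
approximately equal-weight halves for CC½ and `CC* = sqrt(2CC½/(1+CC½))`.

**Absolute scale.** `α = ∫4πs²I_pred ds / ∫4πs²I_meas ds` over the observed
range, both integrals on the same shell binning; the modified predictor
adds the bonding interference
`I_bond(s) = 2Σ f_n f_m sinc(2πs r_nm)` over pairs whose distance follows
from chemical structure alone (peptide bond 1.33 Å; 3 pairs per water, 6
per nitrate from idealized component geometry). Incoherent scattering uses
the independent-electron approximation `S(s) = Z − f(s)²/Z` per atom (zero
at s = 0, → Z at large s) and is subtracted after scaling. The unit-cell
electron count of the study-style inventory computes to 10721 from the
element counts.

**Isotropic separation** resamples the map at the voxels mid-way between
Bragg peaks and sets the isotropic level in each shell to the midpoint
submap's mean minus one standard deviation; the variational map is the full
map minus the radially interpolated level. By construction the variational
map retains a positive offset of about one within-shell standard deviation.

**Dose.** Top-hat beam: rate = flux × E_photon × (μ_en/ρ) / area; with
2.5×10¹⁰ ph/s at 12.693 keV, a 0.1 mm beam and μ_en/ρ = 2.0 cm²/g this
evaluates to 1.3 kGy/s (65 kGy in 50 s), as the acceptance test checks.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the study system at desk scale:
a triclinic P1 cell (the room-temperature lysozyme cell constants by
default), one small rigid molecule per cell grown as a compact chain of
residues, lattice and internal spring networks with planted constants
(contact cutoffs widened automatically until the lattice network restrains
all three lattice directions and the residue graph is connected), a
one-phonon variational map on the standard voxel grid, a broad isotropic
ring peaking near d = 3 Å, and per-voxel Poisson counting with planted
smooth gain fields over a virtual detector. Sizes are deliberately small —
3 residues × 4 atoms, 3–5 subdivisions per axis, hkl up to ~4 — so the full
pipeline runs in minutes on one CPU.

What passing tests therefore show: the estimators recover planted truth at
these statistics, the independent routes (energy-function Hessians,
ensemble sampling, brute-force pair scans, direct Fourier sums) agree with
the analytic implementations, and the bookkeeping identities hold exactly.
What they do not show: behavior on real detector images (metrology,
radiation damage, non-Poisson backgrounds), the absolute magnitudes of real
protein form-factor sums, or statistics that depend on the deposited
experimental maps (headline CC values, measured B-factor averages, fitted
sound velocities of the real crystal).

## Known limitations

- Classical (equipartition) statistics only; no Bose-Einstein occupation.
- One-phonon term only; multi-phonon scattering is neglected, so the
  ensemble-oracle comparison is run in the small-amplitude regime.
- P1 crystals only; no symmetry expansion.
- The internal model's cross-cell covariances are zero by assumption; the
  lattice model carries all intermolecular correlation.
- The KL mask's null behavior masks a few percent of perfect-Poisson voxels
  (see above).
- Patterson compact-support statements are resolution-limited on coarse toy
  grids; tests use shell RMS bounds rather than pointwise ones.
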