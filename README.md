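# diffusekit

Vibrational models and reciprocal-space map processing for protein diffuse
X-ray scattering.

Diffuse (continuous) scattering between and underneath the Bragg peaks of a
protein crystal encodes how atoms move *together*: lattice vibrations produce
intense halos around the reciprocal-lattice nodes, while internal protein
motions contribute short-ranged correlations that only a Patterson (3D-ΔPDF)
analysis can isolate. `diffusekit` implements the full analysis chain for
finely sampled three-dimensional diffuse maps of a triclinic (P1) protein
crystal, at the level of a research pipeline, with every stage exercised on
synthetic crystals with known ground truth:

- **Map construction** — Poisson/Kullback-Leibler integration masking that
  separates Bragg-contaminated voxels from smooth diffuse signal; per-pixel
  corrections (polarization, solid angle, detector efficiency, air path) on a
  virtual flat-panel detector; a multiplicative scaling model
  `I_pred(i) = a(x,y,φ) d(p) [b(φ) I_merge(h) + c(s,φ)]` refined by
  regularized alternating least squares with 5σ outlier rejection;
  inverse-variance merging with Friedel averaging and half-dataset splits for
  CC½/CC*; absolute scaling by the total-intensity (Krogh-Moe) method with a
  bonding-interference correction; isotropic/variational separation.
- **Lattice dynamics** — rigid-body Born/von-Karman models on an elastic
  network of Gaussian and directional springs between the Cα atoms of
  lattice-contact residues; phonon dispersion, sound velocities, displacement
  covariances and ADPs; one-phonon diffuse simulation
  `I₁(s) = kT Σ_m |F₁(s,m)|²/ω_m²` in absolute electron units.
- **Halo analysis and refinement** — per-axis power-law exponents, quadratic
  shape fits `I = [(q−q₀)ᵀ G (q−q₀)]⁻¹` with the anisotropy
  `a = G⊥/G∥ − 1`, and four-stage spring-constant refinement against halo
  intensities with per-halo offsets profiled out analytically.
- **Internal dynamics** — rigid-residue all-atom networks with projection
  operators `P = I − (A\A₀)(A₀\A)` that suppress whole-molecule (or
  per-domain) rigid motion; per-residue coupling constants
  `γ_jj' = sqrt(g_i g_i')` refined against residual ADPs; directional
  correlation maps that expose hinge-bending anti-correlations.
- **Diffuse Patterson** — FFT of experimental maps (missing-voxel fill,
  shell-mean subtraction, zero-padding) and an exact pair-sum model route
  using effective Debye-Waller factors
  `T_eff = T_j T_j' (T_cross − 1)` split additively into lattice and
  internal parts; shell statistics and reciprocal-space CC profiles.
- **Synthetic data** — seeded toy crystals (triclinic lysozyme cell by
  default), planted spring networks, ground-truth one-phonon + isotropic
  maps, and simulated observation sets with planted smooth scale fields and
  Poisson noise.

Scattering vectors use the crystallographic convention |s| = 1/d (Å⁻¹);
`q = 2πs` appears only in presentation-level quantities. Spring constants
default to units of kT/Å², so covariances come out directly in Å².

## Worked example

A minimal lattice-dynamics run on a toy crystal — one rigid unit per
triclinic cell, Gaussian springs to the contacting neighbors:

```python
import numpy as np
from diffusekit import (ToyCrystalSpec, make_toy_crystal, assemble_hessian,
                        compute_covariances, sound_velocities,
                        one_phonon_intensity)
from diffusekit.scattering import ScatteringAtoms

spec = ToyCrystalSpec(seed=1, n_residues=1, atoms_per_residue=1,
                      lattice_cutoff=35.0)
crystal, lattice, _ = make_toy_crystal(spec)
model = assemble_hessian(lattice)
cov = compute_covariances(model, (8, 8, 8))
print(f"isotropic B-factor: {8*np.pi**2*np.trace(cov.adps[0])/3:.2f} A^2")

atoms = ScatteringAtoms.from_crystal(crystal, adps=cov.adps)
m = np.arange(1, 11)
pts = np.array([2.0, 1.0, 1.0]) + np.outer(m / 64.0, [1, 0, 0])
inten = one_phonon_intensity(model, atoms, pts)
print(f"halo exponent along a*: {np.polyfit(np.log(m/64.0), np.log(inten), 1)[0]:.3f}")
```

prints

```
isotropic B-factor: 12.79 A^2
halo exponent along a*: -1.935
```

The B-factor is the classical-equipartition displacement of the rigid unit
on the Born/von-Karman wavevector grid (in Å², for unit spring constants in
kT/Å²), and the halo exponent is the least-squares log–log slope of the
one-phonon intensity profile through the (2,1,1) node — the acoustic-phonon
signature, within the dispersion correction of −2.

## Layout

| module | contents |
| --- | --- |
| `diffusekit.crystal` | unit cells, structure reading (PDB/mmCIF via gemmi), conformer averaging |
| `diffusekit.network` | Gaussian/directional spring networks, lattice and internal builders |
| `diffusekit.dynamics` | rigid-body Hessians, Born/von-Karman solves, covariances, sound speeds |
| `diffusekit.scattering` | structure factors (direct + FFT), Babinet solvent, one-phonon maps, Guinier diffuse |
| `diffusekit.halos` | halo selection, power-law/anisotropy fits, spring refinement, CC/CC* |
| `diffusekit.internal` | rigid-motion projectors, coupling refinement, directional correlations |
| `diffusekit.patterson` | experimental and model diffuse Pattersons, shell statistics |
| `diffusekit.processing` | KL mask, pixel corrections, scaling model, merging, absolute scale, dose |
| `diffusekit.synthetic` | seeded toy crystals, ground-truth maps, simulated observations |

See `docs/methods.md` for the models, conventions and numerical choices.
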