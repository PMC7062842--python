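"""Diffuse Patterson (3D-dPDF) maps: FFT of the diffuse scattering.

The diffuse Patterson is the autocorrelation of the difference electron
density d_rho = rho - <rho>; a vector from the map origin corresponds to an
inter-atomic vector in the crystal.  Experimental maps are transformed by
FFT after missing-voxel filling and shell-mean subtraction; model maps are
built exactly in the central region from the vibrational covariances via
effective Debye-Waller factors

    (T_eff)_{0j,l'j'} = T_j T_j' (T_{0j,l'j'} - 1),
    T_{0j,l'j'} = exp(+4 pi^2 s^T <u_j u_j'^T> s),

split additively into lattice and internal contributions, which makes
Patterson(lattice) + Patterson(internal) = Patterson(combined) exact under
the independence assumption.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.fft import fftn, ifftn, fftshift, ifftshift

from .crystal import NEIGHBOR_TRANSLATIONS, UnitCell
from .maps import MASK_OK, ReciprocalMap

__all__ = [
    "PattersonMap",
    "experimental_patterson",
    "model_patterson",
    "patterson_shell_stats",
    "patterson_reciprocal_cc",
    "fill_missing_voxels",
    "subtract_shell_means",
]


@dataclasses.dataclass
class PattersonMap:
    """Real-space autocorrelation grid, centrosymmetric about the origin.

    ``values[i,j,k]`` corresponds to r = (i - n1//2)/d1 * a + ... with the
    origin at the array center.  ``provenance`` records which component the
    map carries (experimental | lattice | internal | combined).
    """

    cell: UnitCell
    values: np.ndarray
    divisions: tuple[int, int, int]  # real-space voxels per cell edge
    provenance: str = "experimental"

    @property
    def shape(self):
        return self.values.shape

    def r_grid(self) -> np.ndarray:
        """(n1, n2, n3, 3) Cartesian pair vectors of the voxel centers."""
        ax = [
            (np.arange(n) - n // 2) / d
            for n, d in zip(self.values.shape, self.divisions)
        ]
        frac = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
        return self.cell.orthogonalize(frac)

    def r_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.r_grid(), axis=-1)

    def __add__(self, other: "PattersonMap") -> "PattersonMap":
        if self.shape != other.shape:
            raise ValueError("grids differ")
        return PattersonMap(
            self.cell, self.values + other.values, self.divisions, "combined"
        )


def fill_missing_voxels(rmap: ReciprocalMap, max_iter: int = 200) -> np.ndarray:
    """Replace missing/Bragg voxels inside the resolution limit by the mean of
    their 26-neighborhood, iterating until none remain."""
    inten = rmap.intensity.copy()
    smag = rmap.s_magnitude()
    inside = (smag >= rmap.smin) & (smag <= rmap.smax)
    bad = (rmap.mask != MASK_OK) & inside
    frac_bad = bad.sum() / max(inside.sum(), 1)
    if frac_bad > 0.5:
        raise ValueError(f"{frac_bad:.0%} of voxels missing inside the resolution limit")
    good = ~bad
    for _ in range(max_iter):
        if not bad.any():
            break
        acc = np.zeros_like(inten)
        cnt = np.zeros(inten.shape)
        for off in NEIGHBOR_TRANSLATIONS:
            sl_src = tuple(
                slice(max(0, -o), inten.shape[a] - max(0, o))
                for a, o in enumerate(off)
            )
            sl_dst = tuple(
                slice(max(0, o), inten.shape[a] - max(0, -o))
                for a, o in enumerate(off)
            )
            acc[sl_dst] += np.where(good, inten, 0.0)[sl_src]
            cnt[sl_dst] += good[sl_src]
        fillable = bad & (cnt > 0)
        inten[fillable] = acc[fillable] / cnt[fillable]
        good |= fillable
        bad &= ~fillable
    return inten


def subtract_shell_means(rmap: ReciprocalMap, intensity: np.ndarray,
                         ds: float = 0.02) -> np.ndarray:
    """Subtract the mean intensity per resolution shell; zero outside limits."""
    smag = rmap.s_magnitude()
    inside = (smag >= rmap.smin) & (smag <= rmap.smax)
    out = np.zeros_like(intensity)
    edges = np.arange(0.0, smag.max() + ds, ds)
    idx = np.digitize(smag, edges) - 1
    for b in range(len(edges) - 1):
        sel = (idx == b) & inside
        if sel.any():
            out[sel] = intensity[sel] - intensity[sel].mean()
    return out


def _pad_and_fft(rmap: ReciprocalMap, intensity: np.ndarray,
                 divisions: tuple[int, int, int]) -> PattersonMap:
    """Zero-pad the (shell-subtracted) map and FFT to real space.

    The forward transform carries the reciprocal voxel volume so Patterson
    values come out in e^2/A^3 per unit cell.
    """
    sub = rmap.subdivisions
    npad = [d * s for d, s in zip(divisions, sub)]
    for n, cur in zip(npad, rmap.shape):
        if n < cur:
            raise ValueError("target real-space grid too coarse for the map")
    arr = np.zeros(npad, dtype=float)
    # place the centered map into the corner-origin FFT array
    ctr = [sh // 2 for sh in rmap.shape]
    idx = np.ix_(*[
        (np.arange(sh) - c) % n
        for sh, c, n in zip(rmap.shape, ctr, npad)
    ])
    arr[idx] = intensity
    vvox_recip = 1.0 / (rmap.cell.volume * np.prod(sub))
    p = np.real(fftn(arr)) * vvox_recip
    return PattersonMap(rmap.cell, fftshift(p), tuple(divisions), "experimental")


def experimental_patterson(
    rmap: ReciprocalMap,
    divisions: tuple[int, int, int] = (91, 107, 115),
    ds: float = 0.02,
) -> PattersonMap:
    """Patterson of a Friedel-averaged experimental map.

    Missing voxels are filled from their neighbors, shell means are
    subtracted, the array is zero-filled beyond the resolution limit,
    zero-padded to the requested real-space sampling (the study used
    a/91, b/107, c/115, about 0.3 A voxels) and transformed.
    """
    filled = fill_missing_voxels(rmap)
    sub = subtract_shell_means(rmap, filled, ds=ds)
    return _pad_and_fft(rmap, sub, divisions)


def model_patterson(
    atoms,
    cov_latt,
    cov_int=None,
    subdivisions=(13, 11, 11),
    hkl_max=(2, 2, 2),
    divisions=(91, 107, 115),
    cutoff: float = 29.0,
    smin: float = 0.0,
    smax: float = np.inf,
    ds: float = 0.02,
    component: str = "combined",
    kT: float = 1.0,
) -> PattersonMap:
    """Model diffuse Patterson from vibrational covariances (exact pair sum).

    ``atoms`` is a :class:`~diffusekit.scattering.ScatteringAtoms`;
    ``cov_latt``/``cov_int`` are :class:`~diffusekit.dynamics.CovarianceSet`
    objects for the lattice and internal models.  The diffuse intensity is
    accumulated over scatterer pairs across the reference cell and its 26
    neighbors within the distance ``cutoff``, with the effective
    Debye-Waller factors split into lattice and internal parts; the
    resulting reciprocal map goes through the same shell-mean subtraction,
    resolution truncation, padding and FFT as the experimental path.
    ``component`` picks 'lattice', 'internal' or 'combined'.
    """
    if component not in ("lattice", "internal", "combined"):
        raise ValueError(component)
    if component in ("internal", "combined") and cov_int is None:
        warnings.warn("internal covariances missing; computing lattice-only map")
        component = "lattice"
    rmap = ReciprocalMap.empty(atoms.cell, tuple(subdivisions), tuple(hkl_max),
                               smin=smin, smax=smax)
    grid = rmap.frac_grid().reshape(-1, 3)
    s_cart = atoms.cell.s_vector(grid)

    inten = _pair_sum_intensity(atoms, cov_latt, cov_int, s_cart, grid,
                                cutoff, component)
    rmap.intensity = inten.reshape(rmap.shape)
    rmap.mask = np.full(rmap.shape, MASK_OK, dtype=np.uint8)
    sub = subtract_shell_means(rmap, rmap.intensity, ds=ds)
    p = _pad_and_fft(rmap, sub, tuple(divisions))
    p.provenance = component
    return p


def _adp_of(atoms, cov, j):
    grp = cov.model.groups[atoms.group[j]]
    a = grp.projection_row(atoms.positions[j])
    return a @ cov.group_self(int(atoms.group[j])) @ a.T


def _pair_sum_intensity(atoms, cov_latt, cov_int, s_cart, grid, cutoff, component):
    cell = atoms.cell
    n = atoms.n
    f_all = atoms.form_factors(s_cart)  # (nv, n)
    u_latt = np.stack([_adp_of(atoms, cov_latt, j) for j in range(n)])
    u_int = (
        np.stack([_adp_of(atoms, cov_int, j) for j in range(n)])
        if cov_int is not None else np.zeros((n, 3, 3))
    )

    def dwf(u):
        expo = np.einsum("vi,jik,vk->vj", s_cart, u, s_cart)
        return np.exp(-2 * np.pi**2 * expo)

    t_latt = dwf(u_latt)
    t_int = dwf(u_int)
    t_tot = t_latt * t_int

    shifts = np.vstack([[0, 0, 0], NEIGHBOR_TRANSLATIONS])
    inten = np.zeros(len(s_cart))
    frac = cell.fractionalize(atoms.positions)
    for l in shifts:
        shift_cart = np.asarray(l, float) @ cell.orth.T
        for j in range(n):
            dvec = atoms.positions[j] - (atoms.positions + shift_cart)
            dist = np.linalg.norm(dvec, axis=1)
            sel = np.flatnonzero(dist < cutoff)
            if len(sel) == 0:
                continue
            # cross Debye-Waller exponents 4 pi^2 s^T C s per selected partner
            c_latt = np.stack([
                cov_latt.atom_cross(j, jp, tuple(l)) for jp in sel
            ])
            e_latt = np.exp(
                4 * np.pi**2 * np.einsum("vi,pik,vk->vp", s_cart, c_latt, s_cart)
            )
            if component == "lattice":
                t_eff = t_tot[:, [j]] * t_tot[:, sel] * (e_latt - 1.0)
            else:
                # internal motions are intramolecular: cross-cell internal
                # covariances vanish (independent molecules); the Gamma-point
                # solve provides the within-cell blocks
                if tuple(l) == (0, 0, 0):
                    c_int = np.stack([
                        cov_int.atom_cross(j, jp, (0, 0, 0)) for jp in sel
                    ])
                else:
                    c_int = np.zeros((len(sel), 3, 3))
                e_int = np.exp(
                    4 * np.pi**2 * np.einsum("vi,pik,vk->vp", s_cart, c_int, s_cart)
                )
                t_eff_latt = t_tot[:, [j]] * t_tot[:, sel] * (e_latt - 1.0)
                t_eff_int = (
                    t_tot[:, [j]] * t_tot[:, sel] * e_latt * (e_int - 1.0)
                )
                if component == "internal":
                    t_eff = t_eff_int
                else:
                    t_eff = t_eff_latt + t_eff_int
            phase = np.exp(2j * np.pi * (
                (grid @ frac[j])[:, None] - grid @ (frac[sel] + np.asarray(l, float)).T
            ))
            inten += np.real(
                np.sum(f_all[:, [j]] * f_all[:, sel] * t_eff * phase, axis=1)
            )
    return inten


def patterson_shell_stats(p: PattersonMap, dr: float = 0.5, rmax: float | None = None):
    """Standard deviation of the Patterson in spherical pair-distance shells.

    Returns (shell_centers, stddev).
    """
    rmag = p.r_magnitude().ravel()
    vals = p.values.ravel()
    if rmax is None:
        rmax = rmag.max() * 0.7
    edges = np.arange(0.0, rmax + dr, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = np.full(len(centers), np.nan)
    idx = np.digitize(rmag, edges) - 1
    for b in range(len(centers)):
        sel = idx == b
        if sel.sum() >= 2:
            out[b] = vals[sel].std()
    return centers, out


def patterson_reciprocal_cc(
    p_a: PattersonMap,
    p_b: PattersonMap,
    r_window: tuple[float, float] = (2.0, 25.0),
    ds: float = 0.04,
    smin: float = 0.04,
    smax: float = 0.80,
):
    """Reciprocal-space shell CC between two Patterson maps.

    Voxels outside the pair-distance window are zeroed, the maps are
    truncated to |x| < a, |y| < b, |z| < c (2x oversampling in reciprocal
    space), inverse-transformed, and the Pearson CC is computed in shells.
    Returns (shell_centers, cc).
    """
    if p_a.shape != p_b.shape or p_a.divisions != p_b.divisions:
        raise ValueError("Patterson grids differ")
    specs = []
    for p in (p_a, p_b):
        rmag = p.r_magnitude()
        vals = np.where((rmag >= r_window[0]) & (rmag <= r_window[1]), p.values, 0.0)
        # truncate to +-1 cell in fractional units
        sl = []
        for n, d in zip(p.shape, p.divisions):
            ctr = n // 2
            lo = max(ctr - d, 0)
            hi = min(ctr + d, n)
            sl.append(slice(lo, hi))
        vals = vals[tuple(sl)]
        spec = np.abs(ifftn(ifftshift(vals)))
        specs.append(fftshift(spec))
    # fractional index grid of the truncated transform: steps of 1/2 r.l.u.
    shp = specs[0].shape
    ax = [(np.arange(n) - n // 2) / 2.0 for n in shp]
    hkl = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    smag = p_a.cell.s_magnitude(hkl).ravel()
    a, b = specs[0].ravel(), specs[1].ravel()
    edges = np.arange(smin, smax + ds, ds)
    centers = 0.5 * (edges[:-1] + edges[1:])
    cc = np.full(len(centers), np.nan)
    for ib in range(len(centers)):
        sel = (smag >= edges[ib]) & (smag < edges[ib + 1])
        if sel.sum() < 10:
            continue
        x, y = a[sel], b[sel]
        if x.std() == 0 or y.std() == 0:
            continue
        cc[ib] = float(np.corrcoef(x, y)[0, 1])
    return centers, cc
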