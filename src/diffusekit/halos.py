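"""Halo profile analysis and spring-constant refinement.

Halos are the blocks of diffuse intensity surrounding Bragg nodes.  The
analysis tools fit power-law decay exponents and shape anisotropy; the
refinement engine adjusts lattice spring constants to match measured
variational intensities around selected halos, in four stages of
increasing parameter freedom, minimizing the reduced chi-square

    chi2_red = (sum_n M_n)^-1 sum_n sum_m ((I_meas - I_calc - b_n)/sigma)^2

with the per-halo offsets b_n profiled out analytically at each step.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.optimize

from .dynamics import assemble_hessian
from .maps import MASK_OK, ReciprocalMap
from .network import ElasticNetwork
from .scattering import ScatteringAtoms, one_phonon_intensity

__all__ = [
    "HaloBlock",
    "HaloShapeFit",
    "select_halos",
    "fit_power_law",
    "fit_anisotropy",
    "refine_springs",
    "shell_correlation",
    "cc_star",
    "interpolate_to_coarse",
]


@dataclasses.dataclass
class HaloBlock:
    """Measured voxels around one Bragg node (the node voxel excluded)."""

    node: tuple[int, int, int]
    hkl: np.ndarray          # (M_n, 3) fractional indices of the voxels
    intensity: np.ndarray    # (M_n,)
    sigma: np.ndarray        # (M_n,)
    cell: object = None
    offset: float = 0.0      # per-halo constant b_n

    @property
    def m_n(self) -> int:
        return len(self.intensity)

    @property
    def delta(self) -> np.ndarray:
        """Fractional offsets from the central node."""
        return self.hkl - np.asarray(self.node, dtype=float)


def select_halos(
    rmap: ReciprocalMap,
    resolution_window: tuple[float, float],
    count: int,
) -> list[HaloBlock]:
    """The ``count`` most intense halos (by integrated block intensity)
    whose central node lies in the resolution window (s units, 1/angstrom)."""
    smin, smax = resolution_window
    sub = rmap.subdivisions
    hmax = rmap.hkl_max
    half = [s // 2 for s in sub]
    nodes = []
    for h in range(-hmax[0], hmax[0] + 1):
        for k in range(-hmax[1], hmax[1] + 1):
            for l in range(-hmax[2], hmax[2] + 1):
                smag = float(rmap.cell.s_magnitude(np.array([h, k, l], float)))
                if smin <= smag <= smax:
                    nodes.append((h, k, l))
    blocks = []
    ok = rmap.mask == MASK_OK
    for node in nodes:
        hkl, inten, sig = _block_voxels(rmap, node, half, ok)
        if len(inten) == 0:
            continue
        blocks.append(
            HaloBlock(node, hkl, inten, sig, cell=rmap.cell)
        )
    if not blocks:
        warnings.warn("no halo candidates in the requested resolution window")
        return []
    blocks.sort(key=lambda b: -float(b.intensity.sum()))
    if len(blocks) < count:
        warnings.warn(f"only {len(blocks)} halos available (requested {count})")
    return blocks[:count]


def _block_voxels(rmap, node, half, ok):
    """Voxels whose nearest node is ``node``, central Bragg voxel excluded."""
    sub = rmap.subdivisions
    hmax = rmap.hkl_max
    hkl, vals, sigs = [], [], []
    idx0 = [
        (node[a] + hmax[a]) * sub[a] for a in range(3)
    ]
    shape = rmap.shape
    for da in range(-half[0], half[0] + 1):
        for db in range(-half[1], half[1] + 1):
            for dc in range(-half[2], half[2] + 1):
                if (da, db, dc) == (0, 0, 0):
                    continue
                i, j, k = idx0[0] + da, idx0[1] + db, idx0[2] + dc
                if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
                    continue
                if not ok[i, j, k]:
                    continue
                hkl.append(
                    [node[0] + da / sub[0], node[1] + db / sub[1], node[2] + dc / sub[2]]
                )
                vals.append(rmap.intensity[i, j, k])
                sigs.append(rmap.sigma[i, j, k])
    return np.array(hkl).reshape(-1, 3), np.array(vals), np.array(sigs)


def halo_block_from_map(rmap: ReciprocalMap, node) -> HaloBlock:
    half = [s // 2 for s in rmap.subdivisions]
    hkl, inten, sig = _block_voxels(rmap, tuple(node), half, rmap.mask == MASK_OK)
    return HaloBlock(tuple(node), hkl, inten, sig, cell=rmap.cell)


# ---------------------------------------------------------------------------
# power law and anisotropy
# ---------------------------------------------------------------------------

def fit_power_law(block: HaloBlock, axis: int, inner_fraction: float = 0.5):
    """Least-squares log-log slope of the halo profile along one reciprocal axis.

    Points on the two sides of the node are averaged; the per-halo offset
    ``block.offset`` is subtracted first.  Only the inner part of the
    profile (|delta| <= inner_fraction * 0.5 r.l.u.) is used to avoid
    contamination from neighboring halos.  Returns (exponent, stderr).
    """
    delta = block.delta
    on_axis = np.all(
        np.abs(np.delete(delta, axis, axis=1)) < 1e-9, axis=1
    )
    d = delta[on_axis, axis]
    inten = block.intensity[on_axis] - block.offset
    pos = {}
    for di, ii in zip(d, inten):
        key = round(abs(di), 9)
        if key == 0 or key > 0.5 * inner_fraction + 1e-9:
            continue
        pos.setdefault(key, []).append(ii)
    xs, ys = [], []
    for key in sorted(pos):
        val = float(np.mean(pos[key]))
        if val > 0:
            xs.append(key)
            ys.append(val)
    if len(xs) < 4:
        raise ValueError(
            f"fewer than 4 usable profile points along axis {axis} "
            f"({len(xs)} after offset subtraction)"
        )
    lx, ly = np.log(xs), np.log(ys)
    a = np.vstack([lx, np.ones_like(lx)]).T
    coef, res, *_ = np.linalg.lstsq(a, ly, rcond=None)
    dof = max(len(xs) - 2, 1)
    s2 = (res[0] / dof) if len(res) else 0.0
    cov = s2 * np.linalg.inv(a.T @ a)
    return float(coef[0]), float(np.sqrt(max(cov[0, 0], 0.0)))


@dataclasses.dataclass
class HaloShapeFit:
    """Quadratic-form halo shape I = [(q-q0)^T G (q-q0)]^-1 and its anisotropy
    a = G_perp / G_par - 1 (G_par along the scattering vector q0)."""

    g: np.ndarray
    anisotropy: float
    positive_definite: bool


def fit_anisotropy(block: HaloBlock) -> HaloShapeFit:
    """Fit G by linear least squares on 1/I (linear in the 6 components of G)."""
    if block.m_n < 9:
        raise ValueError("need at least 9 voxels to fit a halo shape")
    cell = block.cell
    dq = 2 * np.pi * cell.s_vector(block.delta)  # q = 2 pi s at presentation
    inten = block.intensity - block.offset
    use = inten > 0
    if use.sum() < 9:
        raise ValueError("fewer than 9 positive-intensity voxels")
    dq = dq[use]
    y = 1.0 / inten[use]
    # basis for symmetric G: xx, yy, zz, 2xy, 2xz, 2yz
    b = np.column_stack(
        [
            dq[:, 0] ** 2,
            dq[:, 1] ** 2,
            dq[:, 2] ** 2,
            2 * dq[:, 0] * dq[:, 1],
            2 * dq[:, 0] * dq[:, 2],
            2 * dq[:, 1] * dq[:, 2],
        ]
    )
    coef, *_ = np.linalg.lstsq(b, y, rcond=None)
    g = np.array(
        [
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ]
    )
    evals = np.linalg.eigvalsh(g)
    pd = bool(evals.min() > 0)
    q0 = 2 * np.pi * cell.s_vector(np.asarray(block.node, dtype=float))
    q0hat = q0 / np.linalg.norm(q0)
    g_par = float(q0hat @ g @ q0hat)
    g_perp = float((np.trace(g) - g_par) / 2.0)
    return HaloShapeFit(g=g, anisotropy=g_perp / g_par - 1.0, positive_definite=pd)


# ---------------------------------------------------------------------------
# spring refinement
# ---------------------------------------------------------------------------

def _profiled_offsets(i_meas, i_calc, sigma, halo_id, n_halos):
    """Closed-form weighted-LS offsets b_n per halo."""
    w = 1.0 / sigma**2
    b = np.zeros(n_halos)
    for n in range(n_halos):
        sel = halo_id == n
        b[n] = np.sum(w[sel] * (i_meas[sel] - i_calc[sel])) / np.sum(w[sel])
    return b


def chi2_reduced(i_meas, i_calc, sigma, halo_id, n_halos):
    b = _profiled_offsets(i_meas, i_calc, sigma, halo_id, n_halos)
    r = (i_meas - i_calc - b[halo_id]) / sigma
    return float(np.sum(r**2) / len(r))


@dataclasses.dataclass
class RefinementResult:
    network: ElasticNetwork
    chi2_per_stage: list[float]
    stage_params: list[np.ndarray]


class SpringRefinement:
    """Four-stage spring-constant refinement against halo intensities.

    Stage 1: one Gaussian constant for all springs.
    Stage 2: one Gaussian constant per interface (neighbor translation,
             +-l pairs sharing one interface).
    Stage 3: per-interface Gaussian/directional mixture.
    Stage 4: per-spring mixture.

    Each stage starts from the previous stage's solution; a stage whose
    chi2_red increases beyond tolerance is reverted.
    """

    def __init__(self, network: ElasticNetwork, atoms: ScatteringAtoms,
                 halos: list[HaloBlock], kT: float = 1.0,
                 adp_supercell: tuple[int, int, int] | None = None):
        self.network = network
        self.atoms = atoms
        self.halos = halos
        self.kT = kT
        self.adp_supercell = adp_supercell  # recompute Debye-Waller ADPs per trial
        self.hkl = np.vstack([b.hkl for b in halos])
        self.i_meas = np.concatenate([b.intensity for b in halos])
        self.sigma = np.concatenate([b.sigma for b in halos])
        self.halo_id = np.concatenate(
            [np.full(b.m_n, n) for n, b in enumerate(halos)]
        )
        self.n_halos = len(halos)
        # interface id per edge: neighbor translation, +-l equivalent
        keys = {}
        self.interface = []
        for e in network.edges:
            lk = max(tuple(e.l), tuple(-np.asarray(e.l)))
            self.interface.append(keys.setdefault(lk, len(keys)))
        self.interface = np.array(self.interface)
        self.n_interfaces = len(keys)

    def _set_springs(self, gg: np.ndarray, gd: np.ndarray) -> None:
        for e, a, b in zip(self.network.edges, gg, gd):
            e.gamma_gauss = float(a)
            e.gamma_dir = float(b)

    def _calc(self) -> np.ndarray:
        model = assemble_hessian(self.network)
        if self.adp_supercell is not None:
            from .dynamics import compute_covariances

            cov = compute_covariances(model, self.adp_supercell, kT=self.kT)
            n_atoms = self.network.crystal.n_atoms
            self.atoms.adps[:n_atoms] = cov.adps
        return one_phonon_intensity(model, self.atoms, self.hkl, kT=self.kT)

    def chi2(self, gg, gd) -> float:
        self._set_springs(gg, gd)
        return chi2_reduced(self.i_meas, self._calc(), self.sigma,
                            self.halo_id, self.n_halos)

    def _residuals(self, gg, gd):
        self._set_springs(gg, gd)
        i_calc = self._calc()
        b = _profiled_offsets(self.i_meas, i_calc, self.sigma,
                              self.halo_id, self.n_halos)
        return (self.i_meas - i_calc - b[self.halo_id]) / self.sigma / np.sqrt(
            len(self.i_meas)
        )

    def _optimize(self, pack, unpack, x0, bounds):
        def fun(x):
            gg, gd = unpack(x)
            return self._residuals(gg, gd)

        fit = scipy.optimize.least_squares(
            fun, x0=x0, bounds=bounds, diff_step=1e-3, xtol=1e-12, ftol=1e-12
        )
        return fit.x, float(np.sum(fit.fun**2))

    def run(self, gamma0: float = 1.0, stages=(1, 2, 3, 4),
            revert_tolerance: float = 1e-6) -> RefinementResult:
        ne = len(self.network.edges)
        ni = self.n_interfaces
        chi_hist: list[float] = []
        params_hist: list[np.ndarray] = []
        gamma_i = np.full(ni, gamma0)     # per-interface total constant
        mix_i = np.zeros(ni)              # directional fraction per interface
        gamma_e = None
        mix_e = None
        prev_chi = np.inf

        for stage in stages:
            if stage == 1:
                def unpack(x):
                    g = np.exp(x[0]) * np.ones(ne)
                    return g, np.zeros(ne)

                x, chi = self._optimize(None, unpack,
                                        [np.log(gamma0)],
                                        ([-12.0], [12.0]))
                gamma_i = np.full(ni, np.exp(x[0]))
                mix_i = np.zeros(ni)
            elif stage == 2:
                def unpack(x):
                    g = np.exp(x)[self.interface]
                    return g, np.zeros(ne)

                x, chi = self._optimize(None, unpack,
                                        np.log(gamma_i),
                                        (np.full(ni, -12.0), np.full(ni, 12.0)))
                gamma_i = np.exp(x)
            elif stage == 3:
                def unpack(x):
                    g = np.exp(x[:ni])[self.interface]
                    f = x[ni:][self.interface]
                    return g * (1 - f), g * f

                x0 = np.concatenate([np.log(gamma_i), mix_i])
                lo = np.concatenate([np.full(ni, -12.0), np.zeros(ni)])
                hi = np.concatenate([np.full(ni, 12.0), np.ones(ni)])
                x, chi = self._optimize(None, unpack, x0, (lo, hi))
                gamma_i, mix_i = np.exp(x[:ni]), x[ni:]
                gamma_e = gamma_i[self.interface]
                mix_e = mix_i[self.interface]
            elif stage == 4:
                if gamma_e is None:
                    gamma_e = gamma_i[self.interface]
                    mix_e = mix_i[self.interface]

                def unpack(x):
                    g = np.exp(x[:ne])
                    f = x[ne:]
                    return g * (1 - f), g * f

                x0 = np.concatenate([np.log(gamma_e), mix_e])
                lo = np.concatenate([np.full(ne, -12.0), np.zeros(ne)])
                hi = np.concatenate([np.full(ne, 12.0), np.ones(ne)])
                x, chi = self._optimize(None, unpack, x0, (lo, hi))
                gamma_e, mix_e = np.exp(x[:ne]), x[ne:]
            else:
                raise ValueError(f"unknown stage {stage}")

            if chi > prev_chi * (1 + revert_tolerance):
                warnings.warn(f"stage {stage} increased chi2_red; reverting")
                chi_hist.append(prev_chi)
                continue
            prev_chi = chi
            chi_hist.append(chi)
            if stage <= 2:
                gg, gd = gamma_i[self.interface], np.zeros(ne)
            elif stage == 3:
                gg, gd = gamma_i[self.interface] * (1 - mix_i[self.interface]), \
                    gamma_i[self.interface] * mix_i[self.interface]
            else:
                gg, gd = gamma_e * (1 - mix_e), gamma_e * mix_e
            self._set_springs(gg, gd)
            params_hist.append(np.concatenate([gg, gd]))
        return RefinementResult(self.network, chi_hist, params_hist)


def refine_springs(network, atoms, halos, kT=1.0, gamma0=1.0, stages=(1, 2, 3, 4)):
    """Convenience wrapper around :class:`SpringRefinement`."""
    return SpringRefinement(network, atoms, halos, kT=kT).run(
        gamma0=gamma0, stages=stages
    )


# ---------------------------------------------------------------------------
# correlation statistics and coarse interpolation
# ---------------------------------------------------------------------------

def shell_correlation(
    map_a: ReciprocalMap,
    map_b: ReciprocalMap,
    ds: float = 0.02,
    smin: float = 0.04,
    smax: float = 0.80,
    min_voxels: int = 10,
):
    """Pearson CC per resolution shell over mutually measured voxels.

    Returns (shell_centers, cc); shells with fewer than ``min_voxels``
    common voxels are omitted (NaN).
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    smag = map_a.s_magnitude()
    ok = map_a.observed_mask() & map_b.observed_mask()
    edges = np.arange(smin, smax + ds, ds)
    centers = 0.5 * (edges[:-1] + edges[1:])
    cc = np.full(len(centers), np.nan)
    ia, ib = map_a.intensity[ok], map_b.intensity[ok]
    sm = smag[ok]
    for b in range(len(centers)):
        sel = (sm >= edges[b]) & (sm < edges[b + 1])
        if sel.sum() < min_voxels:
            continue
        x, y = ia[sel], ib[sel]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        cc[b] = float(np.corrcoef(x, y)[0, 1])
    return centers, cc


def cc_star(cc_half):
    """CC* = sqrt(2 CC_1/2 / (1 + CC_1/2)): the maximum CC a model can reach
    given the data's half-dataset correlation."""
    cc_half = np.asarray(cc_half, dtype=float)
    return np.sqrt(2 * cc_half / (1 + cc_half))


def interpolate_to_coarse(
    rmap: ReciprocalMap, target_subdivisions: tuple[int, int, int],
    min_voxels: int = 10,
) -> ReciprocalMap:
    """Resample onto a coarser grid by local quadratic fits.

    Each target voxel takes the value of a second-order polynomial fitted
    over the 3x3x3 source-voxel kernel around it (Bragg and missing source
    voxels excluded); exact for quadratic fields.
    """
    out = ReciprocalMap.empty(
        rmap.cell, tuple(target_subdivisions), rmap.hkl_max,
        smin=rmap.smin, smax=rmap.smax,
    )
    ok = rmap.mask == MASK_OK
    src_ax = rmap.axis_fractions()
    inten = np.full(out.shape, np.nan)
    sub = rmap.subdivisions
    for idx in np.ndindex(out.shape):
        hkl = np.array(
            [ax[i] for ax, i in zip(out.axis_fractions(), idx)]
        )
        ctr = [int(np.rint(hkl[a] * sub[a])) + rmap.hkl_max[a] * sub[a] for a in range(3)]
        pts, vals = [], []
        for da in (-1, 0, 1):
            for db in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    i, j, k = ctr[0] + da, ctr[1] + db, ctr[2] + dc
                    if not all(0 <= x < s for x, s in zip((i, j, k), rmap.shape)):
                        continue
                    if not ok[i, j, k]:
                        continue
                    pts.append([src_ax[0][i], src_ax[1][j], src_ax[2][k]])
                    vals.append(rmap.intensity[i, j, k])
        if len(pts) < min_voxels:
            continue
        d = np.asarray(pts) - hkl
        basis = np.column_stack(
            [
                np.ones(len(d)), d[:, 0], d[:, 1], d[:, 2],
                d[:, 0] ** 2, d[:, 1] ** 2, d[:, 2] ** 2,
                d[:, 0] * d[:, 1], d[:, 0] * d[:, 2], d[:, 1] * d[:, 2],
            ]
        )
        coef, *_ = np.linalg.lstsq(basis, np.asarray(vals), rcond=None)
        inten[idx] = coef[0]
    out.intensity = np.where(np.isnan(inten), 0.0, inten)
    out.mask = np.where(np.isnan(inten), 2, MASK_OK).astype(np.uint8)
    return out
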