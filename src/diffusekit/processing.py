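"""Construction of merged, absolutely scaled diffuse maps from per-image
observations: Poisson/KL integration masking, pixel corrections, scaling
model refinement, merging, Krogh-Moe absolute scaling, isotropic-background
separation and dose arithmetic.

The scaling model relates an observation i to the merged intensity as

    I_pred(i) = a(x_i, y_i, phi_i) d(p_i) [ b(phi_i) I_merge(h_i) + c(s_i, phi_i) ]

where a corrects for absorption, b for illuminated volume/beam intensity,
c (>= 0) for excess isotropic scattering and d for detector-chip
efficiency.  Parameters are fit by alternating regularized linear solves
with 5-sigma outlier rejection in the sequence {b, o, cb, o, c, a, d}.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .formfactors import electron_count, form_factor, incoherent_scattering
from .maps import MASK_MISSING, MASK_OK, ReciprocalMap

__all__ = [
    "CountHistogramGrid",
    "IntegrationMask",
    "kl_integration_mask",
    "DetectorGeometry",
    "apply_pixel_corrections",
    "Observations",
    "ScalingModel",
    "refine_scaling",
    "merge",
    "AbsoluteScale",
    "absolute_scale",
    "bonded_pairs",
    "bonding_correction",
    "isotropic_background",
    "DoseParams",
    "dose_rate",
]


# ---------------------------------------------------------------------------
# KL integration mask
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CountHistogramGrid:
    """Per-voxel histograms of photon counts per pixel on a provisional grid
    (the study subdivides the reciprocal cell by 5 per axis)."""

    shape: tuple[int, int, int]
    histograms: np.ndarray   # (nvox, cmax+1) counts-per-pixel histogram
    multiplicity: np.ndarray  # (nvox,) contributing pixels

    @classmethod
    def from_counts(cls, shape, voxel_of_pixel: np.ndarray, counts: np.ndarray):
        nvox = int(np.prod(shape))
        cmax = int(counts.max()) if len(counts) else 0
        hist = np.zeros((nvox, cmax + 1), dtype=np.int64)
        np.add.at(hist, (voxel_of_pixel, counts.astype(int)), 1)
        return cls(tuple(shape), hist, hist.sum(axis=1))

    def rate(self, v: int) -> float:
        h = self.histograms[v]
        n = h.sum()
        return float((h * np.arange(len(h))).sum() / n) if n else 0.0


@dataclasses.dataclass
class IntegrationMask:
    shape: tuple[int, int, int]
    masked: np.ndarray        # (nvox,) bool, True = removed (Bragg-like)
    delta_kl: np.ndarray      # ranking values at algorithm start


def _poisson_pmf(rate: float, cmax: int, tail: float = 1e-9) -> np.ndarray:
    from scipy.stats import poisson

    upper = int(max(cmax, poisson.ppf(1 - tail, rate) if rate > 0 else 0))
    pmf = poisson.pmf(np.arange(upper + 1), max(rate, 1e-12))
    return pmf[: cmax + 1]


def _kl_to_poisson(hist: np.ndarray, rate: float) -> float:
    n = hist.sum()
    if n == 0:
        return 0.0
    p_obs = hist / n
    pmf = _poisson_pmf(rate, len(hist) - 1)
    nz = p_obs > 0
    return float(np.sum(p_obs[nz] * np.log(p_obs[nz] / np.maximum(pmf[nz], 1e-300))))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def kl_integration_mask(grid: CountHistogramGrid, window_radius: float = 2.0
                        ) -> IntegrationMask:
    """Mask voxels whose exclusion makes their neighborhoods more Poisson-like.

    For each neighborhood (voxels within Euclidean distance <= the window
    radius in grid units), the weighted-median count rate defines a
    reference Poisson law; the KL divergence of the pooled count histogram
    from that law scores the neighborhood.  Voxels are ranked by the change
    Delta_KL their removal causes (ascending, most negative first) and
    masked progressively with neighbor updates but no re-sorting; masking
    halts at the first voxel with Delta_KL >= 0.
    """
    shape = grid.shape
    nvox = int(np.prod(shape))
    r = int(np.floor(window_radius))
    offsets = [
        (i, j, k)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        for k in range(-r, r + 1)
        if i * i + j * j + k * k <= window_radius**2
    ]
    coords = np.stack(np.unravel_index(np.arange(nvox), shape), axis=1)

    def neighborhood(v):
        c = coords[v]
        out = []
        for off in offsets:
            p = c + off
            if np.all((p >= 0) & (p < shape)):
                out.append(int(np.ravel_multi_index(p, shape)))
        return out

    neigh = [neighborhood(v) for v in range(nvox)]
    masked = np.zeros(nvox, dtype=bool)
    rates = np.array([grid.rate(v) for v in range(nvox)])
    base_cache: dict[int, float] = {}

    def neighborhood_kl(center, exclude=None):
        members = [
            m for m in neigh[center]
            if not masked[m] and m != exclude and grid.multiplicity[m] > 0
        ]
        if not members:
            return 0.0
        hist = grid.histograms[members].sum(axis=0)
        weights = grid.multiplicity[members].astype(float)
        rmed = _weighted_median(rates[members], weights)
        return _kl_to_poisson(hist, rmed)

    def base_kl(center):
        if center not in base_cache:
            base_cache[center] = neighborhood_kl(center)
        return base_cache[center]

    def delta_kl(v):
        if grid.multiplicity[v] == 0:
            return 0.0
        tot = 0.0
        for c in neigh[v]:
            tot += neighborhood_kl(c, exclude=v) - base_kl(c)
        return tot

    dkl = np.array([delta_kl(v) for v in range(nvox)])
    order = np.argsort(dkl, kind="stable")
    current = dkl.copy()
    for v in order:
        if masked[v]:
            continue
        if current[v] >= 0:
            break
        masked[v] = True
        # update neighbors sharing a window with v, without re-sorting
        for c in neigh[v]:
            base_cache.pop(c, None)
        affected = set()
        for c in neigh[v]:
            affected.update(neigh[c])
        for w in affected:
            if not masked[w]:
                current[w] = delta_kl(w)
    return IntegrationMask(shape, masked, dkl)


# ---------------------------------------------------------------------------
# virtual detector and pixel corrections
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DetectorGeometry:
    """Flat-panel virtual detector normal to the beam.

    Distances in mm; the beam travels along +z and hits the panel center.
    ``polarization`` is the fraction polarized in the horizontal (x) plane.
    """

    distance: float = 200.0
    pixel_size: float = 0.172
    nx: int = 32
    ny: int = 32
    chip_shape: tuple[int, int] = (4, 4)   # chips tiling the panel
    polarization: float = 0.9
    wavelength: float = 0.9768             # angstroms
    mu_air: float = 0.0                    # 1/mm attenuation of air
    sensor_mu_t: float = 0.0               # detector absorption thickness product

    def pixel_centers(self):
        x = (np.arange(self.nx) - (self.nx - 1) / 2) * self.pixel_size
        y = (np.arange(self.ny) - (self.ny - 1) / 2) * self.pixel_size
        return np.meshgrid(x, y, indexing="ij")

    def chip_index(self):
        cx = (np.arange(self.nx) * self.chip_shape[0]) // self.nx
        cy = (np.arange(self.ny) * self.chip_shape[1]) // self.ny
        return cx[:, None] * self.chip_shape[1] + cy[None, :]

    def scattering_angles(self):
        """(two_theta, azimuth) per pixel."""
        px, py = self.pixel_centers()
        rad = np.hypot(px, py)
        tth = np.arctan2(rad, self.distance)
        az = np.arctan2(py, px)
        return tth, az

    def s_vectors(self, phi: float = 0.0):
        """Scattering vectors (|s| = 1/d) per pixel for spindle angle phi (deg),
        rotation about the lab y axis."""
        px, py = self.pixel_centers()
        d = self.distance
        norm = np.sqrt(px**2 + py**2 + d**2)
        kout = np.stack([px / norm, py / norm, d / norm], axis=-1) / self.wavelength
        kin = np.array([0.0, 0.0, 1.0 / self.wavelength])
        s_lab = kout - kin
        c, sn = np.cos(np.radians(phi)), np.sin(np.radians(phi))
        rot = np.array([[c, 0, sn], [0, 1, 0], [-sn, 0, c]])
        return s_lab @ rot  # crystal-frame s for a rotation of the sample by -phi

    def correction_factors(self):
        """Multiplicative correction that converts measured counts to
        intensity on a common scale: 1 / (polarization * solid angle *
        detector efficiency * air transmission)."""
        tth, az = self.scattering_angles()
        pol = self.polarization * (
            1 - (np.sin(tth) * np.cos(az)) ** 2
        ) + (1 - self.polarization) * (1 - (np.sin(tth) * np.sin(az)) ** 2)
        omega = np.cos(tth) ** 3 * self.pixel_size**2 / self.distance**2
        path = self.distance / np.cos(tth)
        air = np.exp(-self.mu_air * path)
        if self.sensor_mu_t > 0:
            eff = 1 - np.exp(-self.sensor_mu_t / np.cos(tth))
            eff0 = 1 - np.exp(-self.sensor_mu_t)
        else:
            eff = eff0 = 1.0
        omega0 = self.pixel_size**2 / self.distance**2
        return (omega0 / omega) * (1.0 / pol) * (eff0 / eff) * (1.0 / air)


def apply_pixel_corrections(
    frames: np.ndarray,
    geometry: DetectorGeometry,
    background: np.ndarray | None = None,
    variance: np.ndarray | None = None,
):
    """Correct stacked detector images and subtract per-frame background.

    Returns (corrected, sigma).  ``frames`` has shape (nf, nx, ny); the
    background (a crystal-translated-out exposure, same shape or one frame)
    is subtracted frame-by-frame before the multiplicative corrections.
    Poisson variance is propagated unless ``variance`` is given.
    """
    frames = np.asarray(frames, dtype=float)
    corr = geometry.correction_factors()
    if variance is None:
        variance = np.clip(frames, 1.0, None)  # Poisson, floor of one count
    if background is not None:
        background = np.asarray(background, dtype=float)
        frames = frames - background
        variance = variance + np.clip(background, 0.0, None)
    out = frames * corr
    sig2 = variance * corr**2
    if np.any(sig2 < 0):
        raise ValueError("negative corrected variance")
    return out, np.sqrt(sig2)


# ---------------------------------------------------------------------------
# scaling model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Observations:
    """Unmerged observations keyed to merged-map voxels."""

    intensity: np.ndarray
    sigma: np.ndarray
    voxel: np.ndarray       # (n,) int index into the merged map
    phi: np.ndarray         # spindle angle, degrees
    x: np.ndarray           # detector-plane position, fraction of panel [0,1)
    y: np.ndarray
    s: np.ndarray           # |s| of the observation
    chip: np.ndarray        # detector chip index

    def __len__(self):
        return len(self.intensity)


def _interp_matrix(values: np.ndarray, grid: np.ndarray) -> scipy.sparse.csr_matrix:
    """Sparse linear-interpolation matrix mapping grid samples to values."""
    n = len(grid)
    idx = np.clip(np.searchsorted(grid, values) - 1, 0, n - 2)
    t = (values - grid[idx]) / (grid[idx + 1] - grid[idx])
    t = np.clip(t, 0.0, 1.0)
    rows = np.repeat(np.arange(len(values)), 2)
    cols = np.stack([idx, idx + 1], axis=1).ravel()
    vals = np.stack([1 - t, t], axis=1).ravel()
    return scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(values), n)
    )


def _second_diff(n: int) -> scipy.sparse.csr_matrix:
    if n < 3:
        return scipy.sparse.csr_matrix((0, n))
    d = scipy.sparse.diags([1, -2, 1], [0, 1, 2], shape=(n - 2, n))
    return d.tocsr()


class ScalingModel:
    """Eq.-style multiplicative scaling model with regularized grids.

    Grids: ``a`` over (x, y, phi) with bilinear x linear interpolation;
    ``b`` over phi; ``c`` over (s, phi); ``d`` one value per chip.
    """

    def __init__(
        self,
        n_voxels: int,
        phi_range: tuple[float, float],
        nx: int = 9,
        ny: int = 9,
        nphi: int = 26,
        ns: int = 100,
        s_range: tuple[float, float] = (0.0, 0.9132),
        n_chips: int = 960,
        lambda_a: float = 1.0,
        lambda_b: float = 1.0,
        lambda_c: float = 1.0,
        lambda_c_mag: float = 0.1,
        lambda_d: float = 1.0,
    ):
        self.n_voxels = n_voxels
        self.xgrid = np.linspace(0, 1, nx)
        self.ygrid = np.linspace(0, 1, ny)
        self.phigrid = np.linspace(phi_range[0], phi_range[1], nphi)
        self.sgrid = np.linspace(s_range[0], s_range[1], ns)
        self.n_chips = n_chips
        self.a = np.ones(nx * ny * nphi)
        self.b = np.ones(nphi)
        self.c = np.zeros(ns * nphi)
        self.d = np.ones(n_chips)
        self.i_merge = np.zeros(n_voxels)
        self.lam = dict(a=lambda_a, b=lambda_b, c=lambda_c,
                        c_mag=lambda_c_mag, d=lambda_d)

    # -- interpolation operators ----------------------------------------
    def _cached(self, name, obs, builder):
        cache = getattr(self, "_basis_cache", None)
        if cache is None or cache[0] is not obs:
            cache = (obs, {})
            self._basis_cache = cache
        if name not in cache[1]:
            cache[1][name] = builder(obs)
        return cache[1][name]

    def _basis_a(self, obs: Observations) -> scipy.sparse.csr_matrix:
        return self._cached("a", obs, self._build_basis_a)

    def _build_basis_a(self, obs: Observations) -> scipy.sparse.csr_matrix:
        mx = _interp_matrix(obs.x, self.xgrid)
        my = _interp_matrix(obs.y, self.ygrid)
        mp = _interp_matrix(obs.phi, self.phigrid)
        n = len(obs)
        rows, cols, vals = [], [], []
        nx, ny, nphi = len(self.xgrid), len(self.ygrid), len(self.phigrid)
        for m in (mx, my, mp):
            m.sort_indices()
        mxi, myi, mpi = (np.asarray(m.indices).reshape(n, 2) for m in (mx, my, mp))
        mxv, myv, mpv = (np.asarray(m.data).reshape(n, 2) for m in (mx, my, mp))
        for ix in range(2):
            for iy in range(2):
                for ip in range(2):
                    rows.append(np.arange(n))
                    cols.append(
                        (mxi[:, ix] * ny + myi[:, iy]) * nphi + mpi[:, ip]
                    )
                    vals.append(mxv[:, ix] * myv[:, iy] * mpv[:, ip])
        return scipy.sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, nx * ny * nphi),
        )

    def _basis_b(self, obs):
        return self._cached("b", obs, lambda o: _interp_matrix(o.phi, self.phigrid))

    def _basis_c(self, obs):
        return self._cached("c", obs, self._build_basis_c)

    def _build_basis_c(self, obs):
        ms = _interp_matrix(obs.s, self.sgrid)
        mp = _interp_matrix(obs.phi, self.phigrid)
        n = len(obs)
        ns, nphi = len(self.sgrid), len(self.phigrid)
        for m in (ms, mp):
            m.sort_indices()
        msi, mpi = (np.asarray(m.indices).reshape(n, 2) for m in (ms, mp))
        msv, mpv = (np.asarray(m.data).reshape(n, 2) for m in (ms, mp))
        rows, cols, vals = [], [], []
        for i in range(2):
            for j in range(2):
                rows.append(np.arange(n))
                cols.append(msi[:, i] * nphi + mpi[:, j])
                vals.append(msv[:, i] * mpv[:, j])
        return scipy.sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, ns * nphi),
        )

    # -- evaluation ------------------------------------------------------
    def evaluate(self, obs: Observations):
        a = self._basis_a(obs) @ self.a
        b = self._basis_b(obs) @ self.b
        c = self._basis_c(obs) @ self.c
        d = self.d[obs.chip]
        return a, b, c, d

    def predict(self, obs: Observations) -> np.ndarray:
        a, b, c, d = self.evaluate(obs)
        return a * d * (b * self.i_merge[obs.voxel] + c)

    # -- regularizers ----------------------------------------------------
    def _reg_a(self):
        nx, ny, nphi = len(self.xgrid), len(self.ygrid), len(self.phigrid)
        ix = scipy.sparse.identity
        dx = scipy.sparse.kron(scipy.sparse.kron(_second_diff(nx), ix(ny)), ix(nphi))
        dy = scipy.sparse.kron(scipy.sparse.kron(ix(nx), _second_diff(ny)), ix(nphi))
        dp = scipy.sparse.kron(scipy.sparse.kron(ix(nx), ix(ny)), _second_diff(nphi))
        return scipy.sparse.vstack([dx + dy, dp])

    def _reg_c(self):
        ns, nphi = len(self.sgrid), len(self.phigrid)
        ix = scipy.sparse.identity
        dss = scipy.sparse.kron(_second_diff(ns), ix(nphi))
        dpp = scipy.sparse.kron(ix(ns), _second_diff(nphi))
        return scipy.sparse.vstack([dss, dpp])

    # -- block solves ----------------------------------------------------
    def _solve_block(self, basis, target, weights, reg, lam, x0, lower=None,
                     pull_to=None, lam_pull=0.0):
        """Regularized weighted linear least squares for one parameter block."""
        w = scipy.sparse.diags(np.sqrt(weights))
        blocks = [w @ basis]
        rhs = [np.sqrt(weights) * target]
        if reg is not None and reg.shape[0] and lam > 0:
            blocks.append(np.sqrt(lam) * reg)
            rhs.append(np.zeros(reg.shape[0]))
        if pull_to is not None and lam_pull > 0:
            eye = scipy.sparse.identity(basis.shape[1], format="csr")
            blocks.append(np.sqrt(lam_pull) * eye)
            rhs.append(np.sqrt(lam_pull) * pull_to)
        mat = scipy.sparse.vstack(blocks).tocsr()
        rhs = np.concatenate(rhs)
        ata = (mat.T @ mat).toarray()
        atb = mat.T @ rhs
        # tiny ridge keeps unconstrained grid points at their prior value
        sol = np.linalg.solve(ata + 1e-10 * np.eye(len(atb)), atb)
        if lower is not None:
            sol = np.clip(sol, lower, None)
        return sol


def refine_scaling(
    obs: Observations,
    model: ScalingModel,
    sequence: tuple[str, ...] = ("b", "o", "cb", "o", "c", "a", "d"),
    n_cycles: int = 5,
    outlier_sigma: float = 5.0,
    tol: float = 1e-3,
) -> ScalingModel:
    """Alternating refinement of the scaling model.

    Each step solves one parameter block as a regularized linear problem
    with the others fixed, then updates I_merge; 'o' steps reject
    observations more than ``outlier_sigma`` from their prediction.  A
    warning is issued if the relative chi^2 change still exceeds ``tol``
    after ``n_cycles * len(sequence)`` block solves (capped at 50 cycles).
    """
    active = np.ones(len(obs), dtype=bool)
    w_all = 1.0 / obs.sigma**2

    def update_merge():
        a, b, c, d = model.evaluate(obs)
        z = obs.intensity / (a * d) - c
        # weighted LS of z against b per voxel: I = sum w z b / sum w b^2
        num = np.bincount(obs.voxel[active],
                          weights=((a * d) ** 2 * w_all * z * b)[active],
                          minlength=model.n_voxels)
        den = np.bincount(obs.voxel[active],
                          weights=((a * d) ** 2 * w_all * b**2)[active],
                          minlength=model.n_voxels)
        nz = den > 0
        model.i_merge[nz] = num[nz] / den[nz]

    def chi2():
        r = (obs.intensity - model.predict(obs)) / obs.sigma
        return float(np.sum(r[active] ** 2) / max(active.sum(), 1))

    update_merge()
    history = [chi2()]
    n_cycles = min(n_cycles, 50)
    for cycle in range(n_cycles):
        for step in sequence:
            for blk in step:  # 'cb' = c then b
                if blk == "o":
                    pred = model.predict(obs)
                    active = np.abs(obs.intensity - pred) <= outlier_sigma * obs.sigma
                    continue
                a, b, c, d = model.evaluate(obs)
                im = model.i_merge[obs.voxel]
                w = w_all * active
                if blk == "b":
                    basis = model._basis_b(obs)
                    design = scipy.sparse.diags(a * d * im) @ basis
                    target = obs.intensity - a * d * c
                    model.b = model._solve_block(
                        design, target, w, _second_diff(len(model.b)),
                        model.lam["b"], model.b,
                    )
                    # gauge: mean(b) = 1
                    g = model.b.mean()
                    if g > 0:
                        model.b /= g
                        model.i_merge *= g
                elif blk == "c":
                    basis = model._basis_c(obs)
                    design = scipy.sparse.diags(a * d) @ basis
                    target = obs.intensity - a * d * b * im
                    model.c = model._solve_block(
                        design, target, w, model._reg_c(), model.lam["c"],
                        model.c, lower=0.0, pull_to=np.zeros_like(model.c),
                        lam_pull=model.lam["c_mag"],
                    )
                elif blk == "a":
                    basis = model._basis_a(obs)
                    design = scipy.sparse.diags(d * (b * im + c)) @ basis
                    model.a = model._solve_block(
                        design, obs.intensity, w, model._reg_a(),
                        model.lam["a"], model.a, lower=1e-6,
                        pull_to=np.ones_like(model.a), lam_pull=1e-6,
                    )
                elif blk == "d":
                    pred_nod = a * (b * im + c)
                    for p in range(model.n_chips):
                        sel = active & (obs.chip == p)
                        if not sel.any():
                            model.d[p] = 1.0
                            continue
                        num = np.sum(w_all[sel] * obs.intensity[sel] * pred_nod[sel])
                        den = np.sum(w_all[sel] * pred_nod[sel] ** 2)
                        lam = model.lam["d"]
                        model.d[p] = (num + lam) / (den + lam)
                update_merge()
        history.append(chi2())
        if abs(history[-2] - history[-1]) <= tol * max(history[-1], 1e-12):
            break
    else:
        if abs(history[-2] - history[-1]) > tol * max(history[-1], 1e-12):
            warnings.warn(f"scaling refinement not converged; chi2 history {history}")
    model.history = history
    model.active = active
    return model


def merge(
    obs: Observations,
    model: ScalingModel,
    rmap_template: ReciprocalMap,
    outlier_sigma: float = 5.0,
    seed: int = 0,
) -> tuple[ReciprocalMap, ReciprocalMap, ReciprocalMap]:
    """Inverse-variance weighted merge onto the fine grid, plus half-dataset maps.

    Observation intensities are corrected through the scaling model,
    5-sigma outliers (against the weighted mean) are excluded, and the
    unmerged observations are split into halves of approximately equal
    statistical weight (greedy assignment in shuffled order) for CC_1/2.
    """
    a, b, c, d = model.evaluate(obs)
    z = (obs.intensity / (a * d) - c) / b
    sz = obs.sigma / (a * d * b)
    w = 1.0 / sz**2
    nvox = rmap_template.intensity.size

    keep = np.ones(len(obs), dtype=bool)
    for _ in range(2):  # one outlier pass against current means
        num = np.bincount(obs.voxel[keep], weights=(w * z)[keep], minlength=nvox)
        den = np.bincount(obs.voxel[keep], weights=w[keep], minlength=nvox)
        mean = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        keep = np.abs(z - mean[obs.voxel]) <= outlier_sigma * sz

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(obs))
    half_weight = np.zeros((2, nvox))
    half_id = np.zeros(len(obs), dtype=int)
    for i in order:
        v = obs.voxel[i]
        half_id[i] = 0 if half_weight[0, v] <= half_weight[1, v] else 1
        half_weight[half_id[i], v] += w[i]

    def build(sel):
        num = np.bincount(obs.voxel[sel], weights=(w * z)[sel], minlength=nvox)
        den = np.bincount(obs.voxel[sel], weights=w[sel], minlength=nvox)
        out = rmap_template.intensity.copy().ravel()
        sig = np.zeros(nvox)
        msk = np.full(nvox, MASK_MISSING, dtype=np.uint8)
        got = den > 0
        out[got] = num[got] / den[got]
        sig[got] = 1.0 / np.sqrt(den[got])
        msk[got] = MASK_OK
        m = dataclasses.replace(
            rmap_template,
            intensity=out.reshape(rmap_template.shape),
            sigma=sig.reshape(rmap_template.shape),
            mask=msk.reshape(rmap_template.shape),
        )
        return m.friedel_averaged()

    full = build(keep)
    h1 = build(keep & (half_id == 0))
    h2 = build(keep & (half_id == 1))
    return full, h1, h2


# ---------------------------------------------------------------------------
# absolute scale (Krogh-Moe) and bonding correction
# ---------------------------------------------------------------------------

# idealized component geometries for the bonding correction: bonded and
# geometry-restrained pair distances in angstroms
_COMPONENT_PAIRS = {
    # water: two O-H bonds plus the H..H distance (3 pairs)
    "HOH": [("O", "H", 0.9572), ("O", "H", 0.9572), ("H", "H", 1.5139)],
    # nitrate: three N-O bonds plus three O..O distances (6 pairs)
    "NO3": [("N", "O", 1.25)] * 3 + [("O", "O", 2.165)] * 3,
    # planar peptide bond between adjacent residues
    "PEPTIDE": [("C", "N", 1.33)],
}


def bonded_pairs(component: str) -> list[tuple[str, str, float]]:
    """Pair-distance list for a chemical component (per molecule)."""
    try:
        return list(_COMPONENT_PAIRS[component.upper()])
    except KeyError:
        raise ValueError(f"no geometry for component {component!r}") from None


def bonding_correction(pairs, s) -> np.ndarray:
    """I_bond(s) = 2 sum_{n<m} f_n f_m sinc(2 pi s r_nm) for bonded pairs."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    for el1, el2, r in pairs:
        x = 2 * np.pi * s * r
        out += 2 * form_factor(el1, s) * form_factor(el2, s) * np.sinc(x / np.pi)
    return out


@dataclasses.dataclass
class AbsoluteScale:
    alpha: float
    inventory: dict[str, int]
    total_electrons: int
    mode: str


def predicted_total_profile(inventory: dict[str, int], s, pairs=None,
                            include_incoherent=True) -> np.ndarray:
    """Independent-atom total scattering per unit cell: sum_n f_n^2 (+ I_bond)
    (+ incoherent)."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    for el, n in inventory.items():
        out += n * form_factor(el, s) ** 2
        if include_incoherent:
            out += n * incoherent_scattering(el, s)
    if pairs:
        out += bonding_correction(pairs, s)
    return out


def absolute_scale(
    rmap: ReciprocalMap,
    inventory: dict[str, int],
    mode: str = "standard",
    pairs=None,
    s_range: tuple[float, float] = (0.04, 0.5),
    ds: float = 0.01,
    subtract_incoherent: bool = True,
) -> tuple[AbsoluteScale, ReciprocalMap]:
    """Krogh-Moe scale factor alpha = I_total,predicted / I_total,measured.

    Both integrals are total-intensity integrals int 4 pi s^2 I(s) ds over
    the observed range, evaluated on the same shell binning.  In
    ``mode='modified'`` the prediction adds the bonding interference
    I_bond(s) for the supplied pair list.  The returned map is multiplied
    by alpha and (optionally) has the theoretical incoherent scattering
    subtracted.  Doubling all measured intensities halves alpha.
    """
    if mode not in ("standard", "modified"):
        raise ValueError(mode)
    if s_range[1] < 0.5:
        warnings.warn("s_max below 0.5/A: standard-mode convergence is poor")
    centers, means = rmap.shell_means(ds=ds)
    sel = (centers >= s_range[0]) & (centers <= s_range[1]) & np.isfinite(means)
    sc, mc = centers[sel], means[sel]
    meas = np.trapezoid(4 * np.pi * sc**2 * mc, sc)
    pred_prof = predicted_total_profile(
        inventory, sc, pairs=pairs if mode == "modified" else None
    )
    pred = np.trapezoid(4 * np.pi * sc**2 * pred_prof, sc)
    alpha = float(pred / meas)
    z = sum(electron_count(el) * n for el, n in inventory.items())

    scaled = rmap.intensity * alpha
    if subtract_incoherent:
        smag = rmap.s_magnitude()
        incoh = np.zeros_like(smag)
        for el, n in inventory.items():
            incoh += n * incoherent_scattering(el, smag)
        scaled = scaled - incoh
    out = dataclasses.replace(rmap, intensity=scaled,
                              sigma=rmap.sigma * alpha)
    return AbsoluteScale(alpha, dict(inventory), z, mode), out


# ---------------------------------------------------------------------------
# isotropic background separation
# ---------------------------------------------------------------------------

def isotropic_background(rmap: ReciprocalMap, ds: float = 0.02):
    """Split a merged map into an isotropic radial profile and a variational map.

    The map is resampled at the voxels mid-way between Bragg peaks; the
    isotropic level in each resolution bin is the mean minus one standard
    deviation of that midpoint submap.  The variational map is the full map
    minus the radially interpolated isotropic profile.
    Returns (s_centers, iso_profile, variational_map).
    """
    ax = rmap.axis_fractions()
    mid = [np.abs((a * s) % s - s / 2.0) < 0.26 * s for a, s in
           zip(ax, rmap.subdivisions)]
    midmask = mid[0][:, None, None] & mid[1][None, :, None] & mid[2][None, None, :]
    ok = rmap.observed_mask()
    smag = rmap.s_magnitude()
    edges = rmap.shell_bins(ds)
    centers = 0.5 * (edges[:-1] + edges[1:])
    iso = np.full(len(centers), np.nan)
    sel0 = midmask & ok
    for b in range(len(centers)):
        sel = sel0 & (smag >= edges[b]) & (smag < edges[b + 1])
        if sel.sum() >= 2:
            vals = rmap.intensity[sel]
            iso[b] = vals.mean() - vals.std()
    good = np.isfinite(iso)
    prof = np.interp(smag, centers[good], iso[good])
    variational = dataclasses.replace(
        rmap, intensity=np.where(ok, rmap.intensity - prof, 0.0)
    )
    return centers, iso, variational


# ---------------------------------------------------------------------------
# dose
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DoseParams:
    """Top-hat beam dose parameters (study values as defaults)."""

    flux: float = 2.5e10            # photons / s
    beam_diameter_mm: float = 0.1
    photon_energy_kev: float = 12.693
    mu_en_over_rho: float = 2.0     # cm^2 / g

    def __post_init__(self):
        if min(self.flux, self.beam_diameter_mm, self.photon_energy_kev,
               self.mu_en_over_rho) < 0:
            raise ValueError("dose parameters must be non-negative")


def dose_rate(p: DoseParams) -> float:
    """Absorbed dose rate in kGy/s for a top-hat beam."""
    e_joule = p.photon_energy_kev * 1.602176634e-16
    power = p.flux * e_joule                       # W
    area_m2 = np.pi * (p.beam_diameter_mm * 1e-3 / 2) ** 2
    mu_m2_kg = p.mu_en_over_rho * 0.1              # cm^2/g -> m^2/kg
    if area_m2 == 0:
        return 0.0
    return power * mu_m2_kg / area_m2 / 1000.0     # Gy/s -> kGy/s


def cumulative_dose(p: DoseParams, exposure_s: float) -> float:
    """Accumulated dose in kGy after ``exposure_s`` seconds."""
    return dose_rate(p) * exposure_s
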