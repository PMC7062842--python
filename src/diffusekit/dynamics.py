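"""Born/von-Karman rigid-body lattice dynamics on a periodic supercell.

Each rigid group (a whole molecule, or one residue) carries generalized
coordinates: 3 rigid translations plus infinitesimal rotations about its
center of mass along the principal axes of its inertia tensor.  Groups
whose inertia tensor is rank deficient (single atoms, collinear atoms)
carry correspondingly fewer rotational coordinates, which keeps the mass
matrix invertible.

Units: spring constants are interpreted in units of kT/angstrom^2 by
default (``kT = 1``); covariances then come out directly in angstrom^2.
The temperature never needs to be stated separately because the study's
spring constants are refined against absolute intensities.  Frequencies
are reported in the natural unit sqrt(kT/amu)/angstrom; the helper
:func:`frequency_unit_km_per_s` converts slopes d(omega)/d|q| to km/s for
a user-supplied physical temperature.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .network import ElasticNetwork

__all__ = [
    "DynamicalModel",
    "CovarianceSet",
    "DispersionResult",
    "assemble_hessian",
    "solve_phonons",
    "compute_covariances",
    "sound_velocities",
]

#: relative eigenvalue tolerance below which a mode counts as a zero mode
ZERO_MODE_RTOL = 1e-8


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


@dataclasses.dataclass
class RigidGroup:
    """Geometry and generalized-coordinate map of one rigid group."""

    atom_indices: np.ndarray
    com: np.ndarray
    mass: float
    inertia_axes: np.ndarray     # (3, n_rot) principal axes kept
    inertia_moments: np.ndarray  # (n_rot,)

    @property
    def n_dof(self) -> int:
        return 3 + self.inertia_axes.shape[1]

    def projection_row(self, r_atom: np.ndarray) -> np.ndarray:
        """3 x n_dof map from generalized coordinates to the atom displacement.

        Columns: [I3 | axis x (r - com), ...] (TLS/RTB convention).
        """
        d = r_atom - self.com
        cols = [np.eye(3)]
        for a in range(self.inertia_axes.shape[1]):
            cols.append(np.cross(self.inertia_axes[:, a], d)[:, None])
        return np.hstack(cols)

    def mass_matrix(self) -> np.ndarray:
        m = np.zeros((self.n_dof, self.n_dof))
        m[:3, :3] = self.mass * np.eye(3)
        for a, mom in enumerate(self.inertia_moments):
            m[3 + a, 3 + a] = mom
        return m


def _make_groups(network: ElasticNetwork) -> list[RigidGroup]:
    crystal = network.crystal
    masses = crystal.masses()
    heavy = crystal.heavy_mask()
    groups = []
    for g in range(network.n_groups):
        idx = np.flatnonzero(network.groups == g)
        # inertia from non-H atoms only, consistent with network building
        widx = idx[heavy[idx]] if heavy[idx].any() else idx
        m = masses[widx]
        pos = crystal.positions[widx]
        mass = m.sum()
        if mass <= 0:
            raise ValueError(f"group {g} has non-positive mass")
        com = (m[:, None] * pos).sum(axis=0) / mass
        d = pos - com
        inertia = np.zeros((3, 3))
        for mi, di in zip(m, d):
            inertia += mi * ((di @ di) * np.eye(3) - np.outer(di, di))
        evals, evecs = scipy.linalg.eigh(inertia)
        tol = max(evals.max(), 1.0) * 1e-9
        keep = evals > tol
        groups.append(
            RigidGroup(
                atom_indices=idx,
                com=com,
                mass=mass,
                inertia_axes=evecs[:, keep],
                inertia_moments=evals[keep],
            )
        )
    return groups


@dataclasses.dataclass
class DynamicalModel:
    """Assembled rigid-body Hessian of an elastic network.

    ``phi`` maps a lattice translation l to the generalized-coordinate
    force-constant block Phi(l) (n_dof_total x n_dof_total) such that the
    dynamical matrix is D(k) = M^-1/2 [sum_l Phi(l) e^{2 pi i k.l}] M^-1/2.
    The acoustic sum rule (sum_l Phi(l) annihilates uniform translations)
    holds by construction.
    """

    network: ElasticNetwork
    groups: list[RigidGroup]
    phi: dict[tuple[int, int, int], np.ndarray]
    dof_offsets: np.ndarray
    projector: np.ndarray | None = None  # optional generalized-coord projector P

    @property
    def n_dof(self) -> int:
        return int(self.dof_offsets[-1])

    def group_slice(self, g: int) -> slice:
        return slice(int(self.dof_offsets[g]), int(self.dof_offsets[g + 1]))

    def mass_matrix(self) -> np.ndarray:
        m = np.zeros((self.n_dof, self.n_dof))
        for g, grp in enumerate(self.groups):
            m[self.group_slice(g), self.group_slice(g)] = grp.mass_matrix()
        return m

    def _mass_half_inv(self) -> np.ndarray:
        return np.diag(1.0 / np.sqrt(np.diag(self.mass_matrix())))

    def force_constants(self, k) -> np.ndarray:
        """sum_l Phi(l) e^{2 pi i k . l} in generalized coordinates."""
        k = np.asarray(k, dtype=float)
        out = np.zeros((self.n_dof, self.n_dof), dtype=complex)
        for l, block in self.phi.items():
            out += block * np.exp(2j * np.pi * (k @ np.asarray(l, float)))
        if self.projector is not None:
            out = self.projector.T @ out @ self.projector
        return out

    def dynamical_matrix(self, k) -> np.ndarray:
        minv = self._mass_half_inv()
        d = minv @ self.force_constants(k) @ minv
        return 0.5 * (d + d.conj().T)

    def atom_projection(self) -> np.ndarray:
        """Full 3n x n_dof map from generalized coordinates to atom displacements."""
        n = self.network.crystal.n_atoms
        a = np.zeros((3 * n, self.n_dof))
        for g, grp in enumerate(self.groups):
            sl = self.group_slice(g)
            for i in grp.atom_indices:
                a[3 * i : 3 * i + 3, sl] = grp.projection_row(
                    self.network.crystal.positions[i]
                )
        return a


def assemble_hessian(network: ElasticNetwork) -> DynamicalModel:
    """Project the atomic pair Hessians onto rigid-group coordinates.

    For every spring the 3x3 atomic block is K = gamma_gauss*I +
    gamma_dir*rhat rhat^T; the generalized blocks are A^T K A with the
    per-atom rigid-body maps A.
    """
    for e in network.edges:
        if e.gamma_gauss < 0 or e.gamma_dir < 0:
            raise ValueError("negative spring constant")
    groups = _make_groups(network)
    dof_offsets = np.concatenate([[0], np.cumsum([g.n_dof for g in groups])])
    n_dof = int(dof_offsets[-1])
    model = DynamicalModel(network, groups, {}, dof_offsets)

    gidx = network.groups
    crystal = network.crystal
    arow = {}

    def row(atom):
        if atom not in arow:
            arow[atom] = groups[gidx[atom]].projection_row(crystal.positions[atom])
        return arow[atom]

    phi: dict[tuple, np.ndarray] = {}

    def block(l):
        l = tuple(int(x) for x in l)
        if l not in phi:
            phi[l] = np.zeros((n_dof, n_dof))
        return phi[l]

    for e in network.edges:
        kmat = network.pair_hessian(e)
        ga, gb = gidx[e.j], gidx[e.jp]
        aa, ab = row(e.j), row(e.jp)
        sa = model.group_slice(ga)
        sb = model.group_slice(gb)
        block((0, 0, 0))[sa, sa] += aa.T @ kmat @ aa
        block((0, 0, 0))[sb, sb] += ab.T @ kmat @ ab
        lneg = tuple(-x for x in e.l)
        block(e.l)[sa, sb] += -aa.T @ kmat @ ab
        block(lneg)[sb, sa] += -ab.T @ kmat @ aa
    model.phi = phi
    return model


@dataclasses.dataclass
class DispersionResult:
    """Eigenfrequencies and mass-weighted eigenvectors on a wavevector grid."""

    kpoints: np.ndarray          # (nk, 3) fractional r.l.u.
    frequencies: np.ndarray      # (nk, n_dof) omega in sqrt(kT/amu)/angstrom
    eigenvectors: np.ndarray     # (nk, n_dof, n_dof) columns = modes
    model: DynamicalModel

    def acoustic_count(self, ik: int) -> int:
        w2 = self.frequencies[ik] ** 2
        tol = max(w2.max(), 1e-300) * ZERO_MODE_RTOL
        return int(np.sum(w2 <= tol))


def supercell_kgrid(dims: tuple[int, int, int]) -> np.ndarray:
    """Fractional wavevectors of an (n1, n2, n3) Born/von-Karman supercell."""
    n1, n2, n3 = dims
    grids = np.meshgrid(
        np.fft.fftfreq(n1), np.fft.fftfreq(n2), np.fft.fftfreq(n3), indexing="ij"
    )
    return np.stack([g.ravel() for g in grids], axis=1)


def solve_phonons(model: DynamicalModel, kpoints) -> DispersionResult:
    """Diagonalize the mass-weighted dynamical matrix at each wavevector."""
    kpoints = np.atleast_2d(np.asarray(kpoints, dtype=float))
    nk = len(kpoints)
    freqs = np.zeros((nk, model.n_dof))
    vecs = np.zeros((nk, model.n_dof, model.n_dof), dtype=complex)
    for i, k in enumerate(kpoints):
        d = model.dynamical_matrix(k)
        w2, v = scipy.linalg.eigh(d)
        tol = max(abs(w2).max(), 1e-300) * 1e-6
        if w2.min() < -tol:
            raise ValueError(f"non-positive-semidefinite network at k={k}: {w2.min()}")
        freqs[i] = np.sqrt(np.clip(w2, 0.0, None))
        vecs[i] = v
    return DispersionResult(kpoints, freqs, vecs, model)


@dataclasses.dataclass
class CovarianceSet:
    """Classical-equipartition displacement covariances of the network.

    ``cross`` maps a lattice translation l' to the n_dof x n_dof covariance
    between generalized coordinates of the reference cell and of cell l'
    (l' = 0 gives the self covariance).  ``adps`` are per-atom 3x3 U tensors
    in angstrom^2.
    """

    model: DynamicalModel
    cross: dict[tuple[int, int, int], np.ndarray]
    kT: float

    @property
    def self_covariance(self) -> np.ndarray:
        return self.cross[(0, 0, 0)]

    def group_self(self, g: int) -> np.ndarray:
        sl = self.model.group_slice(g)
        return self.self_covariance[sl, sl]

    @property
    def adps(self) -> np.ndarray:
        crystal = self.model.network.crystal
        u = np.zeros((crystal.n_atoms, 3, 3))
        for g, grp in enumerate(self.model.groups):
            cg = self.group_self(g)
            for i in grp.atom_indices:
                a = grp.projection_row(crystal.positions[i])
                u[i] = a @ cg @ a.T
        return u

    def atom_cross(self, j: int, jp: int, l=(0, 0, 0)) -> np.ndarray:
        """3x3 cross covariance <u_j u_j'^T> with atom j' in cell l."""
        l = tuple(int(x) for x in l)
        if l not in self.cross:
            return np.zeros((3, 3))
        model = self.model
        crystal = model.network.crystal
        ga, gb = model.network.groups[j], model.network.groups[jp]
        aj = model.groups[ga].projection_row(crystal.positions[j])
        ajp = model.groups[gb].projection_row(crystal.positions[jp])
        blk = self.cross[l][model.group_slice(ga), model.group_slice(gb)]
        return aj @ blk @ ajp.T

    def debye_waller(self, s_cart: np.ndarray, u: np.ndarray) -> np.ndarray:
        """T(s) = exp(-2 pi^2 s^T U s) for Cartesian s (|s| = 1/d)."""
        return np.exp(-2 * np.pi**2 * np.einsum("...i,jik,...k->...j", s_cart, u, s_cart))


def compute_covariances(
    model: DynamicalModel,
    supercell: tuple[int, int, int],
    kT: float = 1.0,
    translations=((0, 0, 0),),
) -> CovarianceSet:
    """Accumulate kT * D(k)^+ over the supercell wavevector grid.

    Zero modes (eigenvalues below ``ZERO_MODE_RTOL`` times the maximum,
    notably the three acoustic modes at k = 0) are dropped from the
    pseudo-inverse.  ``translations`` selects which cross-cell covariance
    blocks to keep.
    """
    kgrid = supercell_kgrid(supercell)
    nk = len(kgrid)
    minv = model._mass_half_inv()
    translations = [tuple(int(x) for x in l) for l in translations]
    acc = {l: np.zeros((model.n_dof, model.n_dof), dtype=complex) for l in translations}
    for k in kgrid:
        d = model.dynamical_matrix(k)
        w2, v = scipy.linalg.eigh(d)
        tol = max(w2.max(), 0.0) * ZERO_MODE_RTOL
        keep = w2 > tol
        if not keep.any():
            if np.allclose(k, 0.0):
                continue  # pure-translation model: k = 0 carries only acoustic modes
            raise ValueError(f"all modes are zero modes at k={k}")
        vk = v[:, keep]
        pinv = (vk / w2[keep]) @ vk.conj().T
        cov_k = minv @ pinv @ minv
        for l in translations:
            acc[l] += cov_k * np.exp(2j * np.pi * (k @ np.asarray(l, float)))
    cross = {l: (kT / nk) * np.real(a) for l, a in acc.items()}
    return CovarianceSet(model, cross, kT)


@dataclasses.dataclass
class SoundVelocityTable:
    directions: np.ndarray       # (nd, 3) fractional r.l.u. directions
    longitudinal: np.ndarray     # (nd,) natural units (d omega / d|q|)
    transverse_mean: np.ndarray  # (nd,)
    ratio: np.ndarray            # longitudinal / mean transverse


def frequency_unit_km_per_s(temperature_kelvin: float = 295.0) -> float:
    """km/s equivalent of one natural velocity unit sqrt(kT/amu).

    Multiply the natural-unit sound speeds by this factor when the spring
    constants are calibrated in kT/angstrom^2 at the given temperature.
    """
    k_b = 1.380649e-23
    amu = 1.66053906660e-27
    return np.sqrt(k_b * temperature_kelvin / amu) / 1000.0


def sound_velocities(
    model: DynamicalModel,
    directions,
    kmag: float = 0.005,
    npoints: int = 4,
) -> SoundVelocityTable:
    """Acoustic slopes d(omega)/d|q| near k -> 0 along fractional directions.

    q = 2*pi*s is the physical wavevector, so velocities come out in
    (natural frequency unit) * angstrom.  The longitudinal branch is the
    acoustic mode whose polarization is most parallel to k.
    """
    cell = model.network.crystal.cell
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    vlong, vtrans, ratios = [], [], []
    for dirn in directions:
        dirn = dirn / np.linalg.norm(dirn)
        mags = kmag * (np.arange(1, npoints + 1) / npoints)
        slopes = []
        for m in mags:
            k = m * dirn
            d = model.dynamical_matrix(k)
            w2, v = scipy.linalg.eigh(d)
            order = np.argsort(w2)[:3]  # three acoustic branches
            s_cart = cell.s_vector(k)
            q = 2 * np.pi * np.linalg.norm(s_cart)
            khat = s_cart / np.linalg.norm(s_cart)
            pol = []
            for idx in order:
                evec = v[:, idx]
                # translation components across groups, mass weighted
                t = np.zeros(3, dtype=complex)
                for g in range(len(model.groups)):
                    sl = model.group_slice(g)
                    t += evec[sl][:3]
                t = np.abs(np.real(t @ khat.conj())) / max(
                    np.linalg.norm(t), 1e-300
                )
                pol.append(t)
            w = np.sqrt(np.clip(w2[order], 0, None))
            slopes.append((w / q, np.array(pol)))
        v_last = slopes[-1][0]
        pols = slopes[-1][1]
        ilong = int(np.argmax(pols))
        vl = v_last[ilong]
        vt = np.mean(np.delete(v_last, ilong))
        vlong.append(vl)
        vtrans.append(vt)
        ratios.append(vl / vt)
    return SoundVelocityTable(
        directions, np.array(vlong), np.array(vtrans), np.array(ratios)
    )
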