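"""Synthetic crystals, ground-truth diffuse maps and simulated observations.

Everything here emulates the structure of the study system at desk scale:
a triclinic P1 cell (the room-temperature lysozyme cell by default) with
one small rigid molecule per cell, an intermolecular spring network with
known constants, one-phonon halo scattering riding on a broad isotropic
ring (centered near 3 angstrom, where water/short-range disorder scatters),
per-voxel Poisson counting noise, and smooth planted scale/absorption/
offset fields over a virtual detector.  Ground truth is returned alongside
every dataset so recovery tests never need to recompute it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .crystal import TRICLINIC_LYSOZYME_CELL, Crystal, UnitCell
from .dynamics import assemble_hessian, compute_covariances
from .maps import MASK_OK, ReciprocalMap
from .network import ElasticNetwork, build_internal_network, build_lattice_network
from .processing import Observations
from .scattering import ScatteringAtoms, one_phonon_map, structure_factors

__all__ = [
    "ToyCrystalSpec",
    "GroundTruth",
    "make_toy_crystal",
    "ground_truth_map",
    "simulate_observations",
]

_ELEMENTS = ("C", "N", "O")


@dataclasses.dataclass
class ToyCrystalSpec:
    """Parameters of a synthetic crystal with planted dynamics.

    Defaults follow the study conditions where they are stated: the
    triclinic cell, 4 angstrom contact cutoffs, Gaussian lattice springs,
    and an isotropic ring peaking near d = 3 angstrom.
    """

    cell: tuple = TRICLINIC_LYSOZYME_CELL
    n_residues: int = 3
    atoms_per_residue: int = 4
    seed: int = 0
    spread: float = 9.0            # molecule radius scale, angstroms
    lattice_cutoff: float = 4.0
    internal_cutoff: float = 4.0
    gamma_gauss: float = 1.0       # planted lattice spring constant (kT/A^2)
    gamma_dir: float = 0.0
    couplings: float | np.ndarray = 4.0   # planted per-residue couplings
    iso_center_s: float = 1 / 3.0  # isotropic ring center, 1/angstrom
    iso_width_s: float = 0.08
    iso_amplitude: float = 0.0     # electrons^2/cell; 0 = no ring
    max_attempts: int = 10


def _connected(network: ElasticNetwork) -> bool:
    """A one-molecule lattice network is stable iff its edges restrain all
    directions at generic k: check D(k) positive definite at a test point."""
    if not network.edges:
        return False
    if all(e.gamma_gauss == 0 and e.gamma_dir == 0 for e in network.edges):
        return False
    # translations of the contacted neighbors must span all three lattice
    # directions, else whole planes of cells can slide freely
    ls = np.array([e.l for e in network.edges], dtype=float)
    if np.linalg.matrix_rank(ls) < 3:
        return False
    try:
        model = assemble_hessian(network)
        import scipy.linalg

        for k in ((0.21, 0.13, 0.07), (0.05, 0.29, 0.17),
                  (0.25, 0, 0), (0, 0.25, 0), (0, 0, 0.25)):
            w = scipy.linalg.eigvalsh(model.dynamical_matrix(k))
            if w.min() <= 1e-10 * max(w.max(), 1e-300):
                return False
    except Exception:
        return False
    return True


def make_toy_crystal(spec: ToyCrystalSpec):
    """Generate a reproducible toy crystal with lattice and internal networks.

    Returns (crystal, lattice_network, internal_network).  The molecule is
    grown as a loose chain of residues filling the cell so that contacts to
    several of the 26 neighbors arise naturally; generation retries with a
    wider contact cutoff if the planted lattice network is not connected,
    and raises after ``max_attempts``.
    """
    if np.ndim(spec.couplings) and np.any(np.asarray(spec.couplings) < 0):
        raise ValueError("planted couplings must be non-negative")
    if spec.gamma_gauss < 0 or spec.gamma_dir < 0:
        raise ValueError("planted spring constants must be non-negative")
    cell = UnitCell(*spec.cell)
    rng = np.random.default_rng(spec.seed)
    cutoff = spec.lattice_cutoff
    for attempt in range(spec.max_attempts):
        crystal = _random_molecule(cell, spec, rng)
        lattice = build_lattice_network(crystal, cutoff)
        for e in lattice.edges:
            e.gamma_gauss = spec.gamma_gauss
            e.gamma_dir = spec.gamma_dir
        if _connected(lattice):
            internal = _connected_internal(crystal, spec)
            return crystal, lattice, internal
        cutoff *= 1.3
    raise RuntimeError(
        f"could not generate a connected lattice network in {spec.max_attempts} attempts"
    )


def _connected_internal(crystal: Crystal, spec: ToyCrystalSpec) -> ElasticNetwork:
    """Internal network with the cutoff widened until the residue graph is
    connected (single-residue toys are trivially connected)."""
    cutoff = spec.internal_cutoff
    for _ in range(12):
        net = build_internal_network(crystal, cutoff)
        if crystal.n_residues == 1 or _residue_graph_connected(crystal, net):
            return net
        cutoff *= 1.25
    return net


def _residue_graph_connected(crystal: Crystal, net: ElasticNetwork) -> bool:
    res = {int(r): i for i, r in enumerate(crystal.residues)}
    parent = list(range(len(res)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for e in net.edges:
        a = find(res[int(crystal.residue_index[e.j])])
        b = find(res[int(crystal.residue_index[e.jp])])
        parent[a] = b
    return len({find(i) for i in range(len(res))}) == 1


def _random_molecule(cell: UnitCell, spec: ToyCrystalSpec, rng) -> Crystal:
    n_res = spec.n_residues
    n_at = spec.atoms_per_residue
    # residue centers on a compact chain (~4 A steps) starting near a cell
    # corner so lattice contacts to neighboring cells arise
    start = np.array([0.15, 0.15, 0.15]) * np.array([cell.a, cell.b, cell.c])
    centers = [cell.orthogonalize(np.array([0.15, 0.15, 0.15]))]
    step_len = 4.2
    for _ in range(n_res - 1):
        step = rng.standard_normal(3)
        step *= step_len / np.linalg.norm(step)
        nxt = centers[-1] + step
        # reflect back if the chain leaves the central part of the cell
        f = cell.fractionalize(nxt)
        f = np.where(f < 0.08, 0.16 - f, np.where(f > 0.92, 1.84 - f, f))
        centers.append(cell.orthogonalize(f))
    elements, positions, resid, names = [], [], [], []
    for r, ctr in enumerate(centers):
        local = rng.normal(scale=1.3, size=(n_at, 3))
        local[0] = 0.0  # C-alpha at the residue center
        for a in range(n_at):
            elements.append(_ELEMENTS[(r + a) % len(_ELEMENTS)])
            positions.append(ctr + local[a])
            resid.append(r + 1)
            names.append("CA" if a == 0 else f"X{a}")
    return Crystal(
        cell=cell,
        elements=np.array(elements, dtype=object),
        positions=np.array(positions),
        occupancies=np.ones(len(positions)),
        residue_index=np.array(resid),
        atom_names=np.array(names, dtype=object),
    )


def make_hinge_crystal(seed: int = 8, cutoff: float = 7.0):
    """Two compact domains joined by a single hinge residue.

    Emulates the hinge-bending architecture of a two-domain protein: the
    domains (residues 1-4 and 6-9) are spatially separated so no spring
    joins them directly; all coupling passes through the hinge (residue 5).
    Returns (crystal, internal_network, domain_assignment) with domain ids
    0 and 1 for the lobes and 2 for the hinge.
    """
    from .internal import DomainAssignment

    rng = np.random.default_rng(seed)
    cell = UnitCell(*TRICLINIC_LYSOZYME_CELL)
    els, pos, rid, names = [], [], [], []
    for ctr, n_res, res0 in [((8.0, 8, 8), 4, 1), ((13.5, 10, 9), 1, 5),
                             ((19.0, 12, 10), 4, 6)]:
        for i in range(n_res):
            c = np.asarray(ctr) + 2.6 * rng.standard_normal(3)
            local = 1.4 * rng.standard_normal((4, 3))
            local[0] = 0.0
            for a in range(4):
                els.append("C")
                pos.append(c + local[a])
                rid.append(res0 + i)
                names.append("CA" if a == 0 else f"X{a}")
    crystal = Crystal(
        cell=cell,
        elements=np.array(els, dtype=object),
        positions=np.array(pos),
        occupancies=np.ones(len(pos)),
        residue_index=np.array(rid),
        atom_names=np.array(names, dtype=object),
    )
    network = build_internal_network(crystal, cutoff)
    domains = DomainAssignment(
        {int(r): (0 if r <= 4 else (2 if r == 5 else 1)) for r in crystal.residues}
    )
    return crystal, network, domains


@dataclasses.dataclass
class GroundTruth:
    """Noiseless truth for a synthetic dataset."""

    crystal: Crystal
    lattice: ElasticNetwork
    diffuse: ReciprocalMap        # one-phonon variational component
    isotropic: np.ndarray         # per-voxel isotropic ring
    bragg: np.ndarray             # per-node |F|^2 (on the Bragg voxels)
    adps: np.ndarray              # per-atom lattice ADPs
    scale_fields: dict | None = None


def ground_truth_map(
    crystal: Crystal,
    lattice: ElasticNetwork,
    subdivisions=(13, 11, 11),
    hkl_max=(2, 2, 2),
    supercell=None,
    iso_amplitude: float = 0.0,
    iso_center_s: float = 1 / 3.0,
    iso_width_s: float = 0.08,
    kT: float = 1.0,
) -> GroundTruth:
    """One-phonon diffuse map plus isotropic ring and Bragg intensities.

    The Born/von-Karman supercell defaults to the map subdivisions so the
    wavevector mesh matches the voxel grid, as in the study.
    """
    if supercell is None:
        supercell = tuple(subdivisions)
    model = assemble_hessian(lattice)
    cov = compute_covariances(model, supercell, kT=kT)
    adps = cov.adps
    atoms = ScatteringAtoms.from_crystal(crystal, adps=adps)
    rmap = one_phonon_map(model, atoms, tuple(subdivisions), tuple(hkl_max), kT=kT)
    smag = rmap.s_magnitude()
    iso = iso_amplitude * np.exp(-((smag - iso_center_s) ** 2) / (2 * iso_width_s**2))
    bragg_sel = rmap.bragg_voxels()
    hkl_nodes = rmap.frac_grid()[bragg_sel]
    f = structure_factors(atoms, hkl_nodes.reshape(-1, 3))
    bragg = np.abs(f) ** 2
    return GroundTruth(crystal, lattice, rmap, iso, bragg, adps)


def _smooth_field(rng, amplitude: float):
    """Random smooth positive field on [0,1]^n via a low-order Fourier sum."""
    a1, a2, p1, p2 = rng.uniform(0, 2 * np.pi, 4)
    c1, c2 = rng.uniform(0.4, 1.0, 2)

    def field(*coords):
        t = np.zeros(np.broadcast(*coords).shape)
        for i, x in enumerate(coords):
            t = t + c1 * np.sin(2 * np.pi * x * (i + 1) * 0.5 + a1) \
                + c2 * np.cos(2 * np.pi * x * 0.7 + a2 + i)
        t = t / (2 * len(coords))
        return 1.0 + amplitude * t

    return field


def simulate_observations(
    truth: GroundTruth,
    n_obs: int = 4,
    exposure: float = 1.0,
    seed: int = 0,
    field_amplitude: float = 0.3,
    chip_count: int = 16,
    chip_sigma: float = 0.05,
    offset_scale: float = 0.0,
    noise: bool = True,
    phi_range: tuple[float, float] = (0.0, 50.0),
) -> tuple[Observations, dict]:
    """Simulated unmerged observations of the ground-truth map.

    Every OK voxel of the truth map is observed ``n_obs`` times at random
    spindle angles and detector positions; the planted smooth fields a, b
    and planted chip efficiencies d multiply the truth (plus the isotropic
    ring and the offset field c) through the scaling-model forward
    relation, and photon counts are Poisson-drawn at the given exposure
    (counts per intensity unit).  Redundancy across phi plus Friedel
    mates makes the scaling model identifiable.  Returns the observations
    and a dict of the planted fields.
    """
    rng = np.random.default_rng(seed)
    rmap = truth.diffuse
    ok = rmap.mask == MASK_OK
    vox = np.flatnonzero(ok.ravel())
    if n_obs < 2:
        raise ValueError("need n_obs >= 2 for redundancy; scaling is unidentifiable")
    i_true = (rmap.intensity + truth.isotropic).ravel()[vox]
    smag = rmap.s_magnitude().ravel()[vox]

    a_field = _smooth_field(rng, field_amplitude)
    b_field = _smooth_field(rng, field_amplitude)
    d_true = 1.0 + chip_sigma * rng.standard_normal(chip_count)

    nv = len(vox)
    voxel = np.repeat(vox, n_obs)
    i_rep = np.repeat(i_true, n_obs)
    s_rep = np.repeat(smag, n_obs)
    n = len(voxel)
    phi = rng.uniform(*phi_range, n)
    x = rng.uniform(0, 1, n)
    y = rng.uniform(0, 1, n)
    chip = rng.integers(0, chip_count, n)

    a = a_field(x, y, (phi - phi_range[0]) / (phi_range[1] - phi_range[0]))
    b = b_field((phi - phi_range[0]) / (phi_range[1] - phi_range[0]))
    c = offset_scale * np.exp(-((s_rep - 0.3) ** 2) / (2 * 0.1**2))
    d = d_true[chip]
    lam = a * d * (b * i_rep + c) * exposure
    lam = np.clip(lam, 0.0, None)
    if noise:
        counts = rng.poisson(lam)
    else:
        counts = lam
    inten = counts / exposure
    sigma = np.sqrt(np.clip(counts, 1.0, None)) / exposure
    obs = Observations(
        intensity=inten.astype(float),
        sigma=sigma,
        voxel=voxel,
        phi=phi,
        x=x,
        y=y,
        s=s_rep,
        chip=chip,
    )
    fields = dict(a=a_field, b=b_field, d=d_true, c_scale=offset_scale,
                  exposure=exposure, planted_a=a, planted_b=b)
    return obs, fields
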