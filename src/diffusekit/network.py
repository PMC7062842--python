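"""Elastic spring networks between rigid groups across the crystal lattice.

Two pair potentials are supported, acting on the relative displacement
du = u_j - u_j' of the two end-point atoms:

* Gaussian:     V = (1/2) * gamma_gauss * |du|^2
* directional:  V = (1/2) * gamma_dir * (du . rhat)^2

where rhat is the unit vector between the equilibrium end-point positions.
Spring constants carry energy/angstrom^2 units; with the default kT-folded
convention of the dynamics module they are expressed in kT/angstrom^2.

Each physical spring is stored once under a canonical orientation: the
edge (j, j', l) and its lattice image (j', j, -l) are the same spring.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .crystal import NEIGHBOR_TRANSLATIONS, Crystal

__all__ = ["SpringEdge", "ElasticNetwork", "build_lattice_network", "build_internal_network"]


@dataclasses.dataclass
class SpringEdge:
    """A spring between atom ``j`` (reference cell) and atom ``jp`` in cell ``l``."""

    j: int
    jp: int
    l: tuple[int, int, int]
    rhat: np.ndarray
    gamma_gauss: float = 0.0
    gamma_dir: float = 0.0

    def __post_init__(self):
        if self.gamma_gauss < 0 or self.gamma_dir < 0:
            raise ValueError("spring constants must be non-negative")
        self.rhat = np.asarray(self.rhat, dtype=float)
        n = np.linalg.norm(self.rhat)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError("rhat must have unit length")

    def canonical(self) -> "SpringEdge":
        """Return the canonical orientation: j < jp, else l lexicographically positive."""
        flip = False
        if self.j > self.jp:
            flip = True
        elif self.j == self.jp:
            if tuple(self.l) < (0, 0, 0):
                flip = True
        if not flip:
            return self
        return SpringEdge(
            j=self.jp,
            jp=self.j,
            l=tuple(-np.asarray(self.l)),
            rhat=-self.rhat,
            gamma_gauss=self.gamma_gauss,
            gamma_dir=self.gamma_dir,
        )

    def key(self) -> tuple:
        e = self.canonical()
        return (e.j, e.jp, tuple(int(x) for x in e.l))


@dataclasses.dataclass
class ElasticNetwork:
    """A crystal, a rigid-group assignment of its atoms, and spring edges.

    ``groups`` maps each atom to a rigid-group id (0..m-1).  For the lattice
    model there is a single group (the whole molecule); for the internal
    model each residue is a group.  Displacements are Cartesian angstroms
    from equilibrium.
    """

    crystal: Crystal
    groups: np.ndarray            # (n_atoms,) int rigid-group id
    edges: list[SpringEdge]
    kind: str = "lattice"         # "lattice" | "internal"

    def __post_init__(self):
        self.groups = np.asarray(self.groups, dtype=int)
        seen = set()
        canon = []
        for e in self.edges:
            k = e.key()
            if k in seen:
                raise ValueError(f"duplicate edge {k}")
            seen.add(k)
            canon.append(e.canonical())
        self.edges = canon

    @property
    def n_groups(self) -> int:
        return int(self.groups.max()) + 1 if len(self.groups) else 0

    def pair_hessian(self, edge: SpringEdge) -> np.ndarray:
        """3x3 atomic-pair Hessian block: gamma_gauss*I + gamma_dir*rhat rhat^T."""
        r = edge.rhat
        return edge.gamma_gauss * np.eye(3) + edge.gamma_dir * np.outer(r, r)

    def energy(self, displacements: np.ndarray, cell_phase=None) -> float:
        """Potential energy of per-atom displacements, all cells displaced alike.

        ``displacements`` has shape (n_atoms, 3).  With all gammas zero the
        energy is identically zero, and any uniform translation costs nothing.
        """
        u = np.asarray(displacements, dtype=float)
        e_tot = 0.0
        for e in self.edges:
            du = u[e.j] - u[e.jp]
            e_tot += 0.5 * e.gamma_gauss * du @ du
            e_tot += 0.5 * e.gamma_dir * (du @ e.rhat) ** 2
        return float(e_tot)

    def write_table(self, path: str | Path) -> None:
        """Write edges as 'j jp l1 l2 l3 gamma_gauss gamma_dir' text."""
        with open(path, "w") as fh:
            fh.write("# j jp l1 l2 l3 gamma_gauss gamma_dir\n")
            for e in self.edges:
                fh.write(
                    f"{e.j} {e.jp} {e.l[0]} {e.l[1]} {e.l[2]} "
                    f"{e.gamma_gauss:.10g} {e.gamma_dir:.10g}\n"
                )

    @staticmethod
    def read_table(path: str | Path, crystal: Crystal, groups, kind="lattice"):
        edges = []
        shift = crystal.cell.orth
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            j, jp, l1, l2, l3, gg, gd = line.split()
            j, jp, l = int(j), int(jp), (int(l1), int(l2), int(l3))
            d = crystal.positions[jp] + np.array(l, float) @ shift.T - crystal.positions[j]
            edges.append(
                SpringEdge(j, jp, l, d / np.linalg.norm(d), float(gg), float(gd))
            )
        return ElasticNetwork(crystal, groups, edges, kind=kind)


def _contact_pairs(crystal: Crystal, cutoff: float):
    """Yield (atom_i_central, atom_j_neighbor, l) for non-H inter-cell contacts
    between the reference molecule and each of the 26 neighbor cells."""
    heavy = np.flatnonzero(crystal.heavy_mask())
    pos = crystal.positions[heavy]
    tree = cKDTree(pos)
    shifts = crystal.neighbor_shifts_cartesian()
    for l, shift in zip(NEIGHBOR_TRANSLATIONS, shifts):
        ntree = cKDTree(pos + shift)
        for i, js in enumerate(tree.query_ball_tree(ntree, cutoff)):
            for jn in js:
                yield heavy[i], heavy[jn], tuple(int(x) for x in l)


def build_lattice_network(crystal: Crystal, cutoff: float = 4.0) -> ElasticNetwork:
    """Intermolecular C-alpha spring network (rigid group = whole molecule).

    A lattice contact exists between a residue pair (central molecule, one
    of the 26 neighbors) whenever any of their non-H atoms approach within
    ``cutoff``; each contact becomes one spring between the residues'
    C-alpha atoms.  Edges are deduplicated across the +-l lattice symmetry,
    so the unique count is half the raw directed count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = crystal.calpha_index()
    has_ca = len(ca) > 0
    if not has_ca:
        # pseudo-atom toys without CA naming: represent each residue by its
        # first heavy atom instead
        heavy = np.flatnonzero(crystal.heavy_mask())
        for i in heavy[::-1]:
            ca[int(crystal.residue_index[i])] = int(i)
    res_pairs: set[tuple[int, int, tuple]] = set()
    for i, jn, l in _contact_pairs(crystal, cutoff):
        res_pairs.add((int(crystal.residue_index[i]), int(crystal.residue_index[jn]), l))

    orth = crystal.cell.orth
    edges: dict[tuple, SpringEdge] = {}
    for res_i, res_j, l in sorted(res_pairs):
        if has_ca:
            for res in (res_i, res_j):
                if res not in ca:
                    raise ValueError(
                        f"residue {res} in a lattice contact lacks a C-alpha atom"
                    )
        a_j, a_jp = ca[res_i], ca[res_j]
        d = crystal.positions[a_jp] + np.array(l, float) @ orth.T - crystal.positions[a_j]
        nd = np.linalg.norm(d)
        if nd == 0:
            continue
        e = SpringEdge(a_j, a_jp, l, d / nd)
        k = e.key()
        if k not in edges:
            edges[k] = e.canonical()
    groups = np.zeros(crystal.n_atoms, dtype=int)
    return ElasticNetwork(crystal, groups, sorted(edges.values(), key=lambda e: e.key()),
                          kind="lattice")


def build_internal_network(crystal: Crystal, cutoff: float = 4.0) -> ElasticNetwork:
    """All-atom directional spring network with rigid residues.

    Springs join non-H atom pairs of *different* residues within ``cutoff``,
    both inside the reference molecule (l = 0) and across the 26 lattice
    neighbors.  Spring constants are assigned later (geometric mean of
    per-residue couplings); edges are created with zero constants.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = np.flatnonzero(crystal.heavy_mask())
    pos = crystal.positions[heavy]
    res = crystal.residue_index[heavy]
    orth = crystal.cell.orth
    edges: dict[tuple, SpringEdge] = {}

    tree = cKDTree(pos)
    for ii, jj in tree.query_pairs(cutoff):
        if res[ii] == res[jj]:
            continue
        a, b = heavy[ii], heavy[jj]
        d = crystal.positions[b] - crystal.positions[a]
        e = SpringEdge(int(a), int(b), (0, 0, 0), d / np.linalg.norm(d))
        edges.setdefault(e.key(), e.canonical())

    for a, b, l in _contact_pairs(crystal, cutoff):
        d = crystal.positions[b] + np.array(l, float) @ orth.T - crystal.positions[a]
        e = SpringEdge(int(a), int(b), l, d / np.linalg.norm(d))
        edges.setdefault(e.key(), e.canonical())

    # rigid group per residue, numbered 0..m-1 in residue order
    resmap = {r: i for i, r in enumerate(crystal.residues)}
    groups = np.array([resmap[r] for r in crystal.residue_index], dtype=int)
    return ElasticNetwork(crystal, groups, sorted(edges.values(), key=lambda e: e.key()),
                          kind="internal")
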