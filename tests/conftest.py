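import numpy as np
import pytest

from diffusekit import ToyCrystalSpec, make_toy_crystal
from diffusekit.crystal import Crystal, UnitCell


@pytest.fixture
def toy():
    """Small multi-residue toy crystal with lattice + internal networks."""
    spec = ToyCrystalSpec(seed=1)
    crystal, lattice, internal = make_toy_crystal(spec)
    return crystal, lattice, internal


@pytest.fixture
def point_toy():
    """Single rigid unit per cell with isotropic springs to its neighbors:
    a pure-acoustic lattice whose halos decay as |k|^-2."""
    spec = ToyCrystalSpec(seed=1, n_residues=1, atoms_per_residue=1,
                          lattice_cutoff=35.0)
    return make_toy_crystal(spec)


@pytest.fixture
def mini_lattice():
    """Hand-built minimal rigid-molecule lattice: three C-alpha anchor points
    and eight intermolecular springs spanning all lattice directions.
    Compact enough for multi-stage refinement tests."""
    from diffusekit.network import ElasticNetwork, SpringEdge

    cell = UnitCell(27.24, 31.87, 34.23, 88.52, 108.53, 111.89)
    pos = np.array([[4.0, 5.0, 6.0], [12.0, 20.0, 8.0], [20.0, 10.0, 24.0]])
    crystal = Crystal(
        cell=cell,
        elements=np.array(["C", "N", "O"], dtype=object),
        positions=pos,
        occupancies=np.ones(3),
        residue_index=np.array([1, 2, 3]),
        atom_names=np.array(["CA", "CA", "CA"], dtype=object),
    )
    orth = cell.orth

    def edge(j, jp, l):
        d = pos[jp] + np.asarray(l, float) @ orth.T - pos[j]
        return SpringEdge(j, jp, tuple(l), d / np.linalg.norm(d), 1.0, 0.0)

    edges = [
        edge(0, 1, (1, 0, 0)), edge(1, 2, (0, 1, 0)), edge(0, 2, (0, 0, 1)),
        edge(2, 0, (1, 1, 0)), edge(1, 0, (0, 1, 1)), edge(2, 1, (1, 0, 1)),
        edge(0, 0, (1, 0, 0)), edge(1, 1, (0, 1, 0)),
    ]
    network = ElasticNetwork(crystal, np.zeros(3, dtype=int), edges)
    return crystal, network


@pytest.fixture
def cubic_cell():
    return UnitCell(5.0, 5.0, 5.0, 90.0, 90.0, 90.0)


def make_crystal(cell, positions, elements=None, residues=None, names=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if elements is None:
        elements = ["C"] * n
    if residues is None:
        residues = np.arange(1, n + 1)
    if names is None:
        names = [f"X{i}" for i in range(n)]
    return Crystal(
        cell=cell,
        elements=np.array(elements, dtype=object),
        positions=positions,
        occupancies=np.ones(n),
        residue_index=np.asarray(residues),
        atom_names=np.array(names, dtype=object),
    )


@pytest.fixture
def crystal_factory():
    return make_crystal
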