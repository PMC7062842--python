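"""Crystal structures, unit cells and rigid-group bookkeeping.

The package works in Cartesian angstroms internally; fractional coordinates
appear only at I/O boundaries.  Scattering vectors follow the
crystallographic convention |s| = 1/d (so s = h a* + k b* + l c* with
a*.a = 1); any 2*pi/d convention is applied at presentation only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["UnitCell", "Crystal", "load_structure", "NEIGHBOR_TRANSLATIONS"]

#: The 26 lattice translations of the cells adjacent to the reference cell.
NEIGHBOR_TRANSLATIONS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=int,
)

# Room-temperature triclinic lysozyme cell (PDB 4lzt), used as the default
# toy cell so coherence-length and grid bookkeeping match the study system.
TRICLINIC_LYSOZYME_CELL = (27.24, 31.87, 34.23, 88.52, 108.53, 111.89)


@dataclasses.dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell with orthogonalization and reciprocal metrics."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return self._gemmi.volume

    @property
    def orth(self) -> np.ndarray:
        """3x3 matrix whose columns are the cell vectors a, b, c (frac -> Cartesian)."""
        return np.array(self._gemmi.orth.mat.tolist())

    @property
    def frac(self) -> np.ndarray:
        """Inverse of :attr:`orth`; rows are the reciprocal vectors a*, b*, c*."""
        return np.array(self._gemmi.frac.mat.tolist())

    @property
    def reciprocal_vectors(self) -> np.ndarray:
        """Rows a*, b*, c* in inverse angstroms (a*.a = 1 convention)."""
        return self.frac

    def s_vector(self, hkl) -> np.ndarray:
        """Cartesian scattering vector(s) for fractional Miller indices.

        Accepts shape (3,) or (n, 3); |s| = 1/d.
        """
        hkl = np.asarray(hkl, dtype=float)
        return hkl @ self.frac

    def s_magnitude(self, hkl) -> np.ndarray:
        return np.linalg.norm(self.s_vector(hkl), axis=-1)

    def orthogonalize(self, frac_coords) -> np.ndarray:
        return np.asarray(frac_coords, dtype=float) @ self.orth.T

    def fractionalize(self, cart_coords) -> np.ndarray:
        return np.asarray(cart_coords, dtype=float) @ self.frac.T


@dataclasses.dataclass
class Crystal:
    """A P1 crystal: unit cell plus an atom table.

    Atom data is stored column-wise in numpy arrays.  ``residue_index`` is
    the 1-based author residue numbering; ``u_meas`` holds measured ADPs
    (3x3 symmetric, angstrom^2) where available, NaN otherwise.  Alternate
    conformers are collapsed to occupancy-weighted mean positions at load
    time, so each (residue, atom-name) pair appears once.
    """

    cell: UnitCell
    elements: np.ndarray          # (n,) str
    positions: np.ndarray         # (n, 3) Cartesian angstroms
    occupancies: np.ndarray       # (n,)
    residue_index: np.ndarray     # (n,) int
    atom_names: np.ndarray        # (n,) str
    u_meas: np.ndarray | None = None  # (n, 3, 3) or None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.elements = np.asarray(self.elements, dtype=object)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        if np.any((self.occupancies <= 0) | (self.occupancies > 1 + 1e-9)):
            raise ValueError("occupancies must lie in (0, 1]")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def residues(self) -> np.ndarray:
        """Sorted unique residue indices."""
        return np.unique(self.residue_index)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def heavy_mask(self) -> np.ndarray:
        """Mask of non-hydrogen atoms (networks are built from these only)."""
        return np.array([e.upper() not in ("H", "D") for e in self.elements])

    def calpha_index(self) -> dict[int, int]:
        """Residue index -> atom index of its C-alpha (atom name 'CA')."""
        out: dict[int, int] = {}
        for i, (name, res) in enumerate(zip(self.atom_names, self.residue_index)):
            if name == "CA":
                out[int(res)] = i
        return out

    def masses(self) -> np.ndarray:
        return np.array([gemmi.Element(str(e)).weight for e in self.elements])

    def neighbor_shifts_cartesian(self) -> np.ndarray:
        """Cartesian shift vectors of the 26 adjacent cells, shape (26, 3)."""
        return NEIGHBOR_TRANSLATIONS @ self.cell.orth.T


def _merge_alt_conformers(records: list[dict]) -> list[dict]:
    """Collapse alternate conformers to occupancy-weighted mean positions."""
    groups: dict[tuple, list[dict]] = {}
    for rec in records:
        groups.setdefault((rec["res"], rec["name"]), []).append(rec)
    merged = []
    for recs in groups.values():
        if len(recs) == 1 and recs[0]["occ"] >= 1.0 - 1e-9:
            merged.append(recs[0])
            continue
        occ = np.array([r["occ"] for r in recs])
        if occ.sum() <= 0:
            raise ValueError(
                f"residue {recs[0]['res']} atom {recs[0]['name']} has only "
                "zero-occupancy conformers"
            )
        w = occ / occ.sum()
        rec = dict(recs[0])
        rec["pos"] = np.sum([wi * r["pos"] for wi, r in zip(w, recs)], axis=0)
        rec["occ"] = min(float(occ.sum()), 1.0)
        if all(r["u"] is not None for r in recs):
            rec["u"] = np.sum([wi * r["u"] for wi, r in zip(w, recs)], axis=0)
        merged.append(rec)
    merged.sort(key=lambda r: (r["res"], r["serial"]))
    return merged


def load_structure(path: str | Path, conformer_policy: str = "average") -> Crystal:
    """Read a PDB or mmCIF file into a :class:`Crystal`.

    Alternate conformers are merged to occupancy-weighted mean coordinates
    (``conformer_policy='average'``, the only supported policy).  The file
    must carry a unit cell.  Symmetry is expanded to P1 if needed; the study
    crystal is already P1.
    """
    if conformer_policy != "average":
        raise ValueError(f"unknown conformer_policy {conformer_policy!r}")
    st = gemmi.read_structure(str(path))
    cell = st.cell
    if not cell.is_crystal() or cell.volume <= 0 or (
        cell.a == 1 and cell.b == 1 and cell.c == 1
    ):
        raise ValueError(f"{path}: missing or invalid unit cell (no CRYST1?)")
    sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm or "P 1")
    if sg is not None and sg.number != 1:
        raise ValueError(
            f"{path}: space group {st.spacegroup_hm!r} is not P1; "
            "expand the structure to P1 before loading"
        )
    ucell = UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)

    records: list[dict] = []
    model = st[0]
    serial = 0
    for chain in model:
        for residue in chain:
            for atom in residue:
                serial += 1
                u = None
                if atom.aniso.nonzero():
                    u = np.array(
                        [
                            [atom.aniso.u11, atom.aniso.u12, atom.aniso.u13],
                            [atom.aniso.u12, atom.aniso.u22, atom.aniso.u23],
                            [atom.aniso.u13, atom.aniso.u23, atom.aniso.u33],
                        ]
                    )
                elif atom.b_iso > 0:
                    u = np.eye(3) * atom.b_iso / (8 * np.pi**2)
                records.append(
                    dict(
                        res=residue.seqid.num,
                        name=atom.name,
                        element=atom.element.name,
                        pos=np.array(atom.pos.tolist()),
                        occ=atom.occ,
                        u=u,
                        serial=serial,
                    )
                )

    # detect residues present only at zero occupancy before merging
    by_res: dict[int, float] = {}
    for rec in records:
        by_res[rec["res"]] = max(by_res.get(rec["res"], 0.0), rec["occ"])
    for res, occ in by_res.items():
        if occ <= 0:
            raise ValueError(f"residue {res} has only zero-occupancy atoms")

    merged = _merge_alt_conformers(records)
    u_list = [r["u"] for r in merged]
    u_meas = None
    if any(u is not None for u in u_list):
        u_meas = np.stack([u if u is not None else np.full((3, 3), np.nan) for u in u_list])
    return Crystal(
        cell=ucell,
        elements=np.array([r["element"] for r in merged], dtype=object),
        positions=np.array([r["pos"] for r in merged]),
        occupancies=np.array([r["occ"] for r in merged]),
        residue_index=np.array([r["res"] for r in merged]),
        atom_names=np.array([r["name"] for r in merged], dtype=object),
        u_meas=u_meas,
    )
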