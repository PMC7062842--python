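"""Internal protein dynamics: rigid-residue networks with suppressed
whole-molecule (or per-domain) rigid-body motion.

The Hessian of the rigid-residue elastic network is modified as
V := P^T V P where P projects out of the generalized coordinates the
component corresponding to rigid-body displacement of the whole molecule
(or, in the domain-suppressed variant, of each of the alpha/beta/hinge
groups).  The suppressed directions become exact zero modes and are
eliminated by the generalized inversion used for covariances.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.optimize

from .dynamics import (
    DynamicalModel,
    assemble_hessian,
    compute_covariances,
    CovarianceSet,
)
from .network import ElasticNetwork

__all__ = [
    "DomainAssignment",
    "lysozyme_domains",
    "rigid_body_basis",
    "build_projector",
    "build_projected_hessian",
    "assign_couplings",
    "refine_couplings",
    "directional_correlation",
]


@dataclasses.dataclass
class DomainAssignment:
    """Residue -> domain id partition (must cover all residues disjointly)."""

    domains: dict[int, int]  # residue index -> domain id (0..d-1)

    @property
    def n_domains(self) -> int:
        return max(self.domains.values()) + 1

    def of(self, residue: int) -> int:
        return self.domains[residue]


def lysozyme_domains(residues) -> DomainAssignment:
    """The classic lysozyme split: alpha = 5-36 and 98-129, beta = 40-94,
    hinge = remainder (domain ids 0, 1, 2)."""
    out = {}
    for r in residues:
        r = int(r)
        if 5 <= r <= 36 or 98 <= r <= 129:
            out[r] = 0
        elif 40 <= r <= 94:
            out[r] = 1
        else:
            out[r] = 2
    return DomainAssignment(out)


def rigid_body_basis(positions: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """3n x 6 map from rigid translation+rotation (about the center of mass)
    to atomic displacements: rows per atom [I3 | -skew(r - com)]."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if masses is None:
        masses = np.ones(n)
    com = (masses[:, None] * positions).sum(axis=0) / masses.sum()
    a = np.zeros((3 * n, 6))
    for i, r in enumerate(positions):
        d = r - com
        a[3 * i : 3 * i + 3, :3] = np.eye(3)
        a[3 * i : 3 * i + 3, 3:] = -np.array(
            [[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0.0]]
        )
    return a


def build_projector(a: np.ndarray, a_rigid: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """P = I - (A \\ A_r)(A_r \\ A) with least-squares matrix division.

    ``a`` maps generalized coordinates to atomic displacements (3n x g);
    ``a_rigid`` maps the suppressed rigid coordinates to displacements
    (3n x 6 or 3n x 6d).  P acts on generalized coordinates and is
    idempotent to high accuracy.
    """
    x = np.linalg.lstsq(a, a_rigid, rcond=rcond)[0]        # A \ A_r
    y = np.linalg.lstsq(a_rigid, a, rcond=rcond)[0]        # A_r \ A
    p = np.eye(a.shape[1]) - x @ y
    if np.linalg.norm(p @ p - p) > 1e-8 * max(np.linalg.norm(p), 1.0):
        raise ValueError("projector is not idempotent; rigid basis ill-conditioned")
    return p


def build_projected_hessian(
    network: ElasticNetwork,
    suppress: str = "molecule",
    domains: DomainAssignment | None = None,
) -> DynamicalModel:
    """Assemble the rigid-residue Hessian and install the suppression projector.

    ``suppress='molecule'`` removes whole-molecule rigid motion;
    ``suppress='domains'`` removes per-domain rigid motion (requires a
    :class:`DomainAssignment`).  The model is meant to be solved at the
    Gamma point only: intermolecular springs enter with the neighbor
    displacements identified with the central cell's (k = 0).
    """
    model = assemble_hessian(network)
    crystal = network.crystal
    heavy = crystal.heavy_mask()
    masses = crystal.masses()
    a = model.atom_projection()

    if suppress == "molecule":
        a_rigid = rigid_body_basis(crystal.positions, np.where(heavy, masses, 0.0))
    elif suppress == "domains":
        if domains is None:
            raise ValueError("domain suppression requires a DomainAssignment")
        d = domains.n_domains
        a_rigid = np.zeros((3 * crystal.n_atoms, 6 * d))
        for dom in range(d):
            sel = np.array(
                [domains.of(int(r)) == dom for r in crystal.residue_index]
            )
            idx = np.flatnonzero(sel)
            sub = rigid_body_basis(
                crystal.positions[idx], np.where(heavy[idx], masses[idx], 0.0)
            )
            for row, i in enumerate(idx):
                a_rigid[3 * i : 3 * i + 3, 6 * dom : 6 * dom + 6] = sub[
                    3 * row : 3 * row + 3
                ]
    else:
        raise ValueError(f"unknown suppression mode {suppress!r}")

    model.projector = build_projector(a, a_rigid)
    return model


def assign_couplings(network: ElasticNetwork, g: dict[int, float] | np.ndarray) -> None:
    """Set directional spring constants gamma = sqrt(g_i g_i') in place.

    ``g`` maps residue index -> coupling constant (or is an array aligned
    with ``network.crystal.residues``).  Scaling all g by c scales all
    gamma by c; gamma is symmetric in residue exchange.
    """
    crystal = network.crystal
    if not isinstance(g, dict):
        g = dict(zip((int(r) for r in crystal.residues), np.asarray(g, dtype=float)))
    res = crystal.residue_index
    for e in network.edges:
        gi = g[int(res[e.j])]
        gj = g[int(res[e.jp])]
        if gi < 0 or gj < 0:
            raise ValueError("coupling constants must be non-negative")
        e.gamma_dir = float(np.sqrt(gi * gj))
        e.gamma_gauss = 0.0


def internal_adps(
    network: ElasticNetwork,
    g,
    suppress: str = "molecule",
    domains: DomainAssignment | None = None,
    kT: float = 1.0,
) -> tuple[np.ndarray, CovarianceSet]:
    """Per-atom U^int for couplings ``g`` (Gamma-point solve)."""
    assign_couplings(network, g)
    model = build_projected_hessian(network, suppress=suppress, domains=domains)
    cov = compute_covariances(model, (1, 1, 1), kT=kT)
    return cov.adps, cov


@dataclasses.dataclass
class CouplingFit:
    g: np.ndarray              # per-residue couplings, residue order
    residues: np.ndarray
    chi2: float
    cov: CovarianceSet


def refine_couplings(
    network: ElasticNetwork,
    u_meas: np.ndarray,
    u_latt: np.ndarray,
    suppress: str = "molecule",
    domains: DomainAssignment | None = None,
    g0: float = 1.0,
    bounds: tuple[float, float] = (1e-4, 1e4),
    kT: float = 1.0,
    atom_mask: np.ndarray | None = None,
) -> CouplingFit:
    """Fit per-residue couplings to residual ADPs.

    Minimizes chi^2 = sum_atoms sum_9 (U_meas - U_latt - U_int(g))^2 over
    the coupling constants (one per residue), optimized on log g with a
    deterministic start g = g0.  ``atom_mask`` restricts the sum (default:
    non-H atoms).
    """
    crystal = network.crystal
    residues = crystal.residues
    if atom_mask is None:
        atom_mask = crystal.heavy_mask()
    idx = np.flatnonzero(atom_mask)
    target = (u_meas - u_latt)[idx].reshape(len(idx), 9)

    state = {}

    def resid(logg):
        g = np.exp(logg)
        u_int, cov = internal_adps(network, g, suppress=suppress, domains=domains, kT=kT)
        state["cov"] = cov
        return (u_int[idx].reshape(len(idx), 9) - target).ravel()

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    fit = scipy.optimize.least_squares(
        resid,
        x0=np.full(len(residues), np.log(g0)),
        bounds=(lo, hi),
        xtol=1e-10,
        ftol=1e-12,
    )
    g = np.exp(fit.x)
    near_lo = residues[g < bounds[0] * 1.01]
    if len(near_lo):
        import warnings

        warnings.warn(f"couplings at lower bound for residues {list(near_lo)}")
    return CouplingFit(g=g, residues=residues, chi2=float(np.sum(fit.fun**2)),
                       cov=state["cov"])


def directional_correlation(
    cov: CovarianceSet, positions: np.ndarray, atom_pairs
) -> np.ndarray:
    """Directional correlation CC_jj' = rhat^T <u_j u_j'^T> rhat /
    sqrt((Tr U_j / 3)(Tr U_j' / 3)) for the given atom-index pairs."""
    adps = cov.adps
    out = np.full(len(atom_pairs), np.nan)
    for i, (j, jp) in enumerate(atom_pairs):
        tj = np.trace(adps[j]) / 3.0
        tjp = np.trace(adps[jp]) / 3.0
        if tj <= 0 or tjp <= 0:
            continue
        if j == jp:
            out[i] = np.trace(cov.atom_cross(j, jp)) / 3.0 / np.sqrt(tj * tjp)
            continue
        r = positions[jp] - positions[j]
        rhat = r / np.linalg.norm(r)
        c = cov.atom_cross(j, jp)
        out[i] = (rhat @ c @ rhat) / np.sqrt(tj * tjp)
    return out
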