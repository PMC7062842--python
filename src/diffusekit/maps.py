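"""Reciprocal-space map container on a fractional-Miller-index voxel grid.

The grid subdivides the reciprocal cell axes a*, b*, c* by (s1, s2, s3)
(the study uses 13, 11, 11) and extends from -H..H, -K..K, -L..L in integer
Miller indices, so voxel centers sit at fractional indices m/s_i and the
Bragg nodes fall exactly on voxel centers.  Intensities are in electron
units per unit cell once absolutely scaled.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np

from .crystal import UnitCell

__all__ = ["ReciprocalMap", "MASK_OK", "MASK_BRAGG", "MASK_MISSING"]

MASK_OK = 0
MASK_BRAGG = 1
MASK_MISSING = 2


@dataclasses.dataclass
class ReciprocalMap:
    """Voxel grid of diffuse intensity and uncertainty.

    ``mask`` flags each voxel OK (0), Bragg (1) or missing (2).
    """

    cell: UnitCell
    subdivisions: tuple[int, int, int]
    hkl_max: tuple[int, int, int]
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    mask: np.ndarray | None = None
    smin: float = 0.0
    smax: float = np.inf

    def __post_init__(self):
        shape = self.shape
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != shape:
            raise ValueError(f"intensity shape {self.intensity.shape} != grid {shape}")
        if self.sigma is None:
            self.sigma = np.zeros(shape)
        if self.mask is None:
            self.mask = np.full(shape, MASK_OK, dtype=np.uint8)
            self.mask[self.bragg_voxels()] = MASK_BRAGG
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    @classmethod
    def empty(cls, cell, subdivisions, hkl_max, **kw) -> "ReciprocalMap":
        shape = tuple(2 * h * s + 1 for h, s in zip(hkl_max, subdivisions))
        return cls(cell, tuple(subdivisions), tuple(hkl_max),
                   np.zeros(shape), np.zeros(shape), **kw)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            2 * h * s + 1 for h, s in zip(self.hkl_max, self.subdivisions)
        )

    def axis_fractions(self) -> list[np.ndarray]:
        """Fractional Miller indices of voxel centers along each axis."""
        return [
            np.arange(-h * s, h * s + 1) / s
            for h, s in zip(self.hkl_max, self.subdivisions)
        ]

    def frac_grid(self) -> np.ndarray:
        """(n1, n2, n3, 3) array of fractional hkl at voxel centers."""
        ax = self.axis_fractions()
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack(g, axis=-1)

    def s_magnitude(self) -> np.ndarray:
        return self.cell.s_magnitude(self.frac_grid())

    def bragg_voxels(self) -> tuple[np.ndarray, ...]:
        """Index arrays of voxels whose center has integer (h, k, l)."""
        idx = [
            np.flatnonzero(np.arange(-h * s, h * s + 1) % s == 0)
            for h, s in zip(self.hkl_max, self.subdivisions)
        ]
        return tuple(np.meshgrid(*idx, indexing="ij"))

    def voxel_index(self, hkl_frac) -> tuple[np.ndarray, ...]:
        """Grid indices of the voxels containing fractional hkl points."""
        hkl_frac = np.asarray(hkl_frac, dtype=float)
        out = []
        for a, (h, s) in enumerate(zip(self.hkl_max, self.subdivisions)):
            i = np.rint(hkl_frac[..., a] * s).astype(int) + h * s
            if np.any((i < 0) | (i >= 2 * h * s + 1)):
                raise IndexError("fractional hkl outside map bounds")
            out.append(i)
        return tuple(out)

    def observed_mask(self) -> np.ndarray:
        """OK voxels inside the resolution window."""
        smag = self.s_magnitude()
        return (self.mask == MASK_OK) & (smag >= self.smin) & (smag <= self.smax)

    def friedel_averaged(self) -> "ReciprocalMap":
        """Average each voxel with its Friedel mate I(s) <- (I(s)+I(-s))/2."""
        inten = self.intensity.copy()
        flip = inten[::-1, ::-1, ::-1]
        ok = self.mask == MASK_OK
        okf = ok[::-1, ::-1, ::-1]
        both = ok & okf
        out = np.where(both, 0.5 * (inten + flip), np.where(ok, inten, flip))
        sig = self.sigma.copy()
        sigf = sig[::-1, ::-1, ::-1]
        sout = np.where(both, np.sqrt(sig**2 + sigf**2) / 2, np.where(ok, sig, sigf))
        mask = np.where(ok | okf, MASK_OK, self.mask).astype(np.uint8)
        mask[self.bragg_voxels()] = self.mask[self.bragg_voxels()]
        return dataclasses.replace(self, intensity=out, sigma=sout, mask=mask)

    # -- shells ----------------------------------------------------------
    def shell_bins(self, ds: float = 0.02, smin=None, smax=None):
        smin = self.smin if smin is None else smin
        smax = min(self.smax, self.s_magnitude().max()) if smax is None else smax
        edges = np.arange(smin, smax + ds, ds)
        return edges

    def shell_means(self, ds: float = 0.02):
        """Per-shell mean intensity over OK voxels; returns (centers, means)."""
        edges = self.shell_bins(ds)
        smag = self.s_magnitude()
        ok = self.observed_mask()
        idx = np.digitize(smag[ok], edges) - 1
        nsh = len(edges) - 1
        means = np.full(nsh, np.nan)
        vals = self.intensity[ok]
        for b in range(nsh):
            sel = idx == b
            if sel.any():
                means[b] = vals[sel].mean()
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, means

    # -- I/O -------------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("intensity", data=self.intensity, chunks=True)
            fh.create_dataset("sigma", data=self.sigma, chunks=True)
            fh.create_dataset("mask", data=self.mask, chunks=True)
            fh.attrs["cell"] = [
                self.cell.a, self.cell.b, self.cell.c,
                self.cell.alpha, self.cell.beta, self.cell.gamma,
            ]
            fh.attrs["subdivisions"] = self.subdivisions
            fh.attrs["hkl_max"] = self.hkl_max
            fh.attrs["smin"] = self.smin
            fh.attrs["smax"] = self.smax if np.isfinite(self.smax) else -1.0
            fh.attrs["scale_convention"] = "electron units per unit cell; |s|=1/d"

    @classmethod
    def load(cls, path) -> "ReciprocalMap":
        with h5py.File(path, "r") as fh:
            cell = UnitCell(*fh.attrs["cell"])
            smax = float(fh.attrs["smax"])
            return cls(
                cell,
                tuple(int(x) for x in fh.attrs["subdivisions"]),
                tuple(int(x) for x in fh.attrs["hkl_max"]),
                fh["intensity"][()],
                fh["sigma"][()],
                fh["mask"][()],
                smin=float(fh.attrs["smin"]),
                smax=np.inf if smax < 0 else smax,
            )

    def to_text(self, path) -> None:
        """Plain-text (h_frac, k_frac, l_frac, I, sigma) exporter."""
        grid = self.frac_grid().reshape(-1, 3)
        with open(path, "w") as fh:
            fh.write("# h k l intensity sigma\n")
            for (h, k, l), inten, sig, m in zip(
                grid,
                self.intensity.ravel(),
                self.sigma.ravel(),
                self.mask.ravel(),
            ):
                if m == MASK_OK:
                    fh.write(f"{h:.6f} {k:.6f} {l:.6f} {inten:.8g} {sig:.8g}\n")
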