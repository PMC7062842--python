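"""Atomic scattering factors and incoherent (Compton) scattering.

Elastic form factors use the standard four-Gaussian-plus-constant
parameterization (International Tables c4.3.3, via gemmi's IT92 table):

    f(s) = sum_i a_i exp(-b_i (s/2)^2) + c,     s = 1/d.

Incoherent scattering per atom is modeled with the independent-electron
approximation S(s) = Z - f(s)^2 / Z, which vanishes at s = 0 and tends to
Z at large s.
"""

from __future__ import annotations

import gemmi
import numpy as np

__all__ = ["form_factor", "electron_count", "incoherent_scattering"]


def _it92(element: str):
    el = gemmi.Element(element)
    coef = el.it92
    if el.atomic_number == 0 or coef is None:
        raise ValueError(f"no form factor tabulated for element {element!r}")
    return np.asarray(coef.a), np.asarray(coef.b), coef.c


def electron_count(element: str) -> int:
    z = gemmi.Element(element).atomic_number
    if z == 0:
        raise ValueError(f"unknown element {element!r}")
    return z


def form_factor(element: str, s) -> np.ndarray:
    """Elastic scattering factor f(s) in electrons, s = 1/d in 1/angstrom."""
    a, b, c = _it92(element)
    stol2 = (np.asarray(s, dtype=float) / 2.0) ** 2
    return np.sum(a * np.exp(-b * stol2[..., None]), axis=-1) + c


def incoherent_scattering(element: str, s) -> np.ndarray:
    """Per-atom incoherent (Compton) intensity S(s) in electron units."""
    z = electron_count(element)
    f = form_factor(element, s)
    return z - f**2 / z
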