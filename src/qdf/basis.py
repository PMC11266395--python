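"""Gaussian basis sets and contracted Cartesian basis functions.

The embedded tables are the standard Pople-series parameters: STO-3G for
H/C/N/O and split-valence 6-31G for H.  STO-3G contraction coefficients are
the universal Slater-fit values; exponents are the zeta-scaled, per-element
published constants.  These small tables are all the engine needs for the
toy molecules (H2, H2O, distorted variants) that drive the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import BOHR_PER_ANGSTROM, ELEMENT_Z

# shell data: element -> list of (l, exponents, coefficients)
_STO3G_1S = (0.1543289673, 0.5353281423, 0.4446345422)
_STO3G_2S = (-0.09996722919, 0.3995128261, 0.7001154689)
_STO3G_2P = (0.1559162750, 0.6076837186, 0.3919573931)

BASIS_LIBRARY: dict[str, dict[str, list[tuple[int, tuple, tuple]]]] = {
    "sto-3g": {
        "H": [(0, (3.425250914, 0.6239137298, 0.1688554040), _STO3G_1S)],
        "C": [
            (0, (71.61683735, 13.04509632, 3.530512160), _STO3G_1S),
            (0, (2.941249355, 0.6834830964, 0.2222899159), _STO3G_2S),
            (1, (2.941249355, 0.6834830964, 0.2222899159), _STO3G_2P),
        ],
        "N": [
            (0, (99.10616896, 18.05231239, 4.885660238), _STO3G_1S),
            (0, (3.780455879, 0.8784966449, 0.2857143744), _STO3G_2S),
            (1, (3.780455879, 0.8784966449, 0.2857143744), _STO3G_2P),
        ],
        "O": [
            (0, (130.7093214, 23.80886605, 6.443608313), _STO3G_1S),
            (0, (5.033151319, 1.169596125, 0.3803889600), _STO3G_2S),
            (1, (5.033151319, 1.169596125, 0.3803889600), _STO3G_2P),
        ],
    },
    "6-31g": {
        "H": [
            (0, (18.73113696, 2.825394365, 0.6401216923),
                (0.03349460434, 0.2347269535, 0.8137573261)),
            (0, (0.1612777588,), (1.0,)),
        ],
    },
}


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, powers: tuple[int, int, int]) -> float:
    """Normalization constant of a primitive Cartesian Gaussian."""
    i, j, k = powers
    l = i + j + k
    pre = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = np.sqrt(
        _double_factorial(2 * i - 1)
        * _double_factorial(2 * j - 1)
        * _double_factorial(2 * k - 1)
    )
    return pre / den


@dataclass
class BasisFunction:
    """A contracted Cartesian Gaussian basis function.

    ``coefs`` already include primitive normalization and an overall
    contraction normalization so that <phi|phi> = 1.
    """

    center: np.ndarray          # Bohr
    powers: tuple[int, int, int]
    exps: np.ndarray
    coefs: np.ndarray
    atom_index: int

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.exps = np.asarray(self.exps, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float)


_CART_POWERS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}


def _contracted_self_overlap(exps, coefs, powers) -> float:
    i, j, k = powers
    acc = 0.0
    for a, ca in zip(exps, coefs):
        for b, cb in zip(exps, coefs):
            p = a + b
            s = (np.pi / p) ** 1.5
            s *= _double_factorial(2 * i - 1) * _double_factorial(2 * j - 1) \
                * _double_factorial(2 * k - 1) / (2.0 * p) ** (i + j + k)
            acc += ca * cb * s
    return acc


def build_basis(geometry, basis_name: str) -> list[BasisFunction]:
    """Expand a geometry into contracted Cartesian basis functions.

    ``geometry`` is a list of (symbol, (x, y, z)) with coordinates in
    Angstrom.  Raises ``KeyError``-derived configuration errors for unknown
    bases or elements.
    """
    name = basis_name.lower()
    if name not in BASIS_LIBRARY:
        raise ValueError(f"unknown basis set: {basis_name!r}")
    table = BASIS_LIBRARY[name]
    funcs: list[BasisFunction] = []
    for iatom, (sym, xyz) in enumerate(geometry):
        sym = sym.capitalize()
        if sym not in ELEMENT_Z:
            raise ValueError(f"unknown element: {sym!r}")
        if sym not in table:
            raise ValueError(f"basis {basis_name!r} has no data for element {sym!r}")
        center = np.asarray(xyz, dtype=float) * BOHR_PER_ANGSTROM
        for l, exps, coefs in table[sym]:
            for powers in _CART_POWERS[l]:
                e = np.asarray(exps, float)
                c = np.asarray(coefs, float) * np.array(
                    [primitive_norm(a, powers) for a in exps]
                )
                c = c / np.sqrt(_contracted_self_overlap(e, c, powers))
                funcs.append(BasisFunction(center, powers, e, c, iatom))
    return funcs
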