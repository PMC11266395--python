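"""Determinant-basis full CI within a small orbital space.

Used both as the CASCI solver (exact solution within the active space) and,
at tiny sizes, as the reference the variational quantum emulation is tested
against.  Determinants are (alpha, beta) occupation bitmasks over spatial
orbitals; two-electron integrals are chemists' (pq|rs).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import eigh


def alpha_strings(norb: int, nelec: int) -> list[int]:
    """All occupation bitmasks of ``nelec`` electrons in ``norb`` orbitals."""
    return [sum(1 << i for i in occ) for occ in combinations(range(norb), nelec)]


def _occ_list(string: int, norb: int):
    return [i for i in range(norb) if string >> i & 1]


def _excite(string: int, q: int, p: int):
    """Apply a^dag_p a_q to a string; return (new_string, phase) or None."""
    if not string >> q & 1:
        return None
    s1 = string & ~(1 << q)
    if s1 >> p & 1:
        return None
    # phase: electrons between min and max of (p, q) in intermediate string
    lo, hi = (p, q) if p < q else (q, p)
    mask = ((1 << hi) - 1) & ~((1 << (lo + 1)) - 1)
    phase = -1.0 if bin(s1 & mask).count("1") % 2 else 1.0
    return s1 | (1 << p), phase


def spin_excitation_matrices(norb: int, nelec: int):
    """Dense matrices of a^dag_p a_q acting on same-spin strings.

    Returns dict (p, q) -> (nstr, nstr) matrix in the string basis.
    """
    strings = alpha_strings(norb, nelec)
    index = {s: i for i, s in enumerate(strings)}
    n = len(strings)
    mats = {}
    for p in range(norb):
        for q in range(norb):
            m = np.zeros((n, n))
            for j, s in enumerate(strings):
                res = _excite(s, q, p)
                if res is not None:
                    m[index[res[0]], j] = res[1]
            mats[(p, q)] = m
    return mats


class FCISpace:
    """Full CI space for (na, nb) electrons in ``norb`` spatial orbitals."""

    def __init__(self, norb: int, na: int, nb: int):
        self.norb, self.na, self.nb = norb, na, nb
        self.str_a = alpha_strings(norb, na)
        self.str_b = alpha_strings(norb, nb)
        self.dim = len(self.str_a) * len(self.str_b)
        self._ea = spin_excitation_matrices(norb, na)
        self._eb = spin_excitation_matrices(norb, nb)

    def e_pq(self, p: int, q: int) -> np.ndarray:
        """Spin-summed excitation operator E_pq = sum_sigma a^dag_p a_q
        as a dense matrix over the determinant basis."""
        na, nb = len(self.str_a), len(self.str_b)
        out = np.kron(self._ea[(p, q)], np.eye(nb))
        out += np.kron(np.eye(na), self._eb[(p, q)])
        return out

    def hamiltonian(self, h: np.ndarray, eri: np.ndarray) -> np.ndarray:
        """Dense Hamiltonian sum h_pq E_pq + 1/2 (pq|rs)(E_pq E_rs - d_qr E_ps)."""
        norb = self.norb
        H = np.zeros((self.dim, self.dim))
        E = {}
        for p in range(norb):
            for q in range(norb):
                E[(p, q)] = self.e_pq(p, q)
                H += h[p, q] * E[(p, q)]
        for p in range(norb):
            for q in range(norb):
                for r in range(norb):
                    for s in range(norb):
                        g = eri[p, q, r, s]
                        if abs(g) < 1e-14:
                            continue
                        H += 0.5 * g * (E[(p, q)] @ E[(r, s)])
                        if q == r:
                            H -= 0.5 * g * E[(p, s)]
        return H

    def rdm12(self, civec: np.ndarray):
        """Spin-summed 1- and 2-RDM of a CI vector.

        Conventions: rdm1[p,q] = <E_pq>;
        rdm2[p,q,r,s] = <E_pq E_rs> - d_qr <E_ps>, so the electronic energy
        is sum(h*rdm1) + 0.5*sum(eri*rdm2) with chemists' eri.
        """
        norb = self.norb
        c = civec
        rdm1 = np.zeros((norb, norb))
        Ec = {}
        for p in range(norb):
            for q in range(norb):
                Ec[(p, q)] = self.e_pq(p, q) @ c
                rdm1[p, q] = c @ Ec[(p, q)]
        rdm2 = np.zeros((norb,) * 4)
        for p in range(norb):
            for q in range(norb):
                for r in range(norb):
                    for s in range(norb):
                        val = Ec[(q, p)] @ Ec[(r, s)]
                        if q == r:
                            val -= rdm1[p, s]
                        rdm2[p, q, r, s] = val
        return rdm1, rdm2


def fci_ground_state(h, eri, norb, na, nb):
    """Lowest eigenpair plus degeneracy flag.

    Returns (energy, civec, degenerate).
    """
    space = FCISpace(norb, na, nb)
    H = space.hamiltonian(h, eri)
    w, v = eigh(H)
    degenerate = bool(len(w) > 1 and w[1] - w[0] < 1e-10)
    return float(w[0]), v[:, 0], degenerate, space
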