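"""FCIDUMP (Molpro dialect) reader and writer.

FCIDUMP's native two-electron convention is chemists' (pq|rs) with 8-fold
real-orbital permutational symmetry, which is also this package's in-memory
convention, so the mapping is the identity and is asserted on round trip.
One-electron integrals are stored as (p q 0 0), the scalar core/nuclear
energy as (0 0 0 0); indices are 1-based.
"""

from __future__ import annotations

import re

import numpy as np

from .core import ActiveHamiltonian


def write_fcidump(path, h: np.ndarray, eri: np.ndarray, e_core: float,
                  n_elec: int, ms2: int = 0, tol: float = 0.0):
    n = h.shape[0]
    with open(path, "w") as fh:
        fh.write(f"&FCI NORB={n},NELEC={n_elec},MS2={ms2},\n")
        fh.write("  ORBSYM=" + "1," * n + "\n")
        fh.write("  ISYM=1,\n&END\n")
        for p in range(n):
            for q in range(p + 1):
                for r in range(p + 1):
                    s_max = q if r == p else r
                    for s in range(s_max + 1):
                        val = eri[p, q, r, s]
                        if abs(val) > tol:
                            fh.write(f" {val:23.16e} {p+1:4d} {q+1:4d} {r+1:4d} {s+1:4d}\n")
        for p in range(n):
            for q in range(p + 1):
                if abs(h[p, q]) > tol:
                    fh.write(f" {h[p, q]:23.16e} {p+1:4d} {q+1:4d}    0    0\n")
        fh.write(f" {e_core:23.16e}    0    0    0    0\n")


def write_active_hamiltonian(path, ham: ActiveHamiltonian):
    write_fcidump(path, ham.h_eff, ham.eri_active, ham.e_core,
                  ham.n_active_elec)


def read_fcidump(path):
    """Returns (h, eri, e_core, n_elec) with full symmetry unfolded."""
    with open(path) as fh:
        text = fh.read()
    header, _, body = text.partition("&END")
    if not body:
        header, _, body = text.partition("/")  # some dialects end with /
    m = re.search(r"NORB\s*=\s*(\d+)", header)
    n = int(m.group(1))
    m = re.search(r"NELEC\s*=\s*(\d+)", header)
    n_elec = int(m.group(1))
    h = np.zeros((n, n))
    eri = np.zeros((n, n, n, n))
    e_core = 0.0
    for line in body.strip().splitlines():
        parts = line.split()
        if len(parts) != 5:
            continue
        val = float(parts[0])
        p, q, r, s = (int(x) for x in parts[1:])
        if p == q == r == s == 0:
            e_core = val
        elif r == s == 0:
            h[p - 1, q - 1] = h[q - 1, p - 1] = val
        else:
            p, q, r, s = p - 1, q - 1, r - 1, s - 1
            for (a, b) in ((p, q), (q, p)):
                for (c, d) in ((r, s), (s, r)):
                    eri[a, b, c, d] = eri[c, d, a, b] = val
    return h, eri, e_core, n_elec


def read_active_hamiltonian(path) -> ActiveHamiltonian:
    h, eri, e_core, n_elec = read_fcidump(path)
    return ActiveHamiltonian(h_eff=h, eri_active=eri, e_core=e_core,
                             n_active_orb=h.shape[0], n_active_elec=n_elec)
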