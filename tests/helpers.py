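"""Independent oracles shared across the test suite.

The fermionic dense-matrix oracle builds ladder operators as explicit
Kronecker-product matrices on the full Fock space -- a construction
independent of the package's symbolic Pauli algebra and of its
determinant-basis CI, so spectra computed here are a genuine cross-check.
"""

import numpy as np

from qdf.core import ActiveHamiltonian


def random_active_hamiltonian(n_orb, seed, e_core=0.0, n_elec=2,
                              scale=0.3) -> ActiveHamiltonian:
    rng = np.random.default_rng(seed)
    h = rng.normal(size=(n_orb, n_orb))
    h = 0.5 * (h + h.T)
    M = rng.normal(size=(n_orb**2, n_orb**2)) * scale
    eri = (M @ M.T).reshape(n_orb, n_orb, n_orb, n_orb)
    eri = 0.5 * (eri + eri.transpose(1, 0, 2, 3))
    eri = 0.5 * (eri + eri.transpose(0, 1, 3, 2))
    eri = 0.5 * (eri + eri.transpose(2, 3, 0, 1))
    return ActiveHamiltonian(h_eff=h, eri_active=eri, e_core=e_core,
                             n_active_orb=n_orb, n_active_elec=n_elec)


def fermionic_ladder_matrices(n_modes):
    """a_j on the 2^n Fock space with Jordan-Wigner sign strings."""
    lower = np.array([[0.0, 1.0], [0.0, 0.0]])
    Z = np.diag([1.0, -1.0])
    I = np.eye(2)
    ops = []
    for j in range(n_modes):
        mats = [Z] * j + [lower] + [I] * (n_modes - j - 1)
        out = np.array([[1.0]])
        for m in mats:
            out = np.kron(out, m)
        ops.append(out)
    return ops


def fermionic_hamiltonian_matrix(ham: ActiveHamiltonian):
    """Dense Fock-space matrix of the active Hamiltonian (blocked spins)."""
    no = ham.n_active_orb
    n = 2 * no
    a = fermionic_ladder_matrices(n)
    ad = [m.T for m in a]

    def so(p, s):
        return p + s * no

    H = np.zeros((2**n, 2**n))
    for p in range(no):
        for q in range(no):
            if abs(ham.h_eff[p, q]) > 1e-14:
                for s in (0, 1):
                    H += ham.h_eff[p, q] * ad[so(p, s)] @ a[so(q, s)]
    for p in range(no):
        for q in range(no):
            for r in range(no):
                for s_ in range(no):
                    g = ham.eri_active[p, q, r, s_]
                    if abs(g) < 1e-14:
                        continue
                    for sg in (0, 1):
                        for tu in (0, 1):
                            H += 0.5 * g * (ad[so(p, sg)] @ ad[so(r, tu)]
                                            @ a[so(s_, tu)] @ a[so(q, sg)])
    return H


def particle_number_matrix(n_modes):
    a = fermionic_ladder_matrices(n_modes)
    return sum(m.T @ m for m in a)


WATER_GEOMETRY = [("O", (0.0, 0.0, 0.1173)),
                  ("H", (0.0, 0.7572, -0.4692)),
                  ("H", (0.0, -0.7572, -0.4692))]

H3PLUS_GEOMETRY = [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.95)),
                   ("H", (0.0, 0.83, 0.31))]
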