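"""Restricted Hartree-Fock with DIIS acceleration.

Small dense implementation intended for the few-atom QM regions this
package targets.  Supports an additive one-electron perturbation (MM
point-charge embedding or a continuum-solvent reaction field) via
``h_extra`` and, for solvated SCF, a callable producing a density-dependent
one-electron term plus its energy bookkeeping.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh


class SCFConvergenceError(RuntimeError):
    def __init__(self, n_iter, err):
        super().__init__(
            f"SCF failed to converge in {n_iter} iterations "
            f"(last DIIS error {err:.3e})")
        self.n_iter = n_iter
        self.err = err


def fock_2e(eri, D):
    """Coulomb-exchange contribution G(D) for a closed-shell density D."""
    J = np.einsum("pqrs,rs->pq", eri, D)
    K = np.einsum("prqs,rs->pq", eri, D)
    return J - 0.5 * K


def rhf(S, hcore, eri, n_elec, e_nuc=0.0, *, max_iter=200, conv_tol=1e-10,
        density_term=None):
    """Solve closed-shell RHF.

    Parameters
    ----------
    density_term : optional callable D -> (v, e_term).  ``v`` is a
        density-dependent one-electron operator entering the Fock matrix
        (e.g. a COSMO reaction field, v = dE_s/dD) and ``e_term`` is that
        interaction's total energy E_s(D), added to the electronic energy
        as E = Tr(D h) + 1/2 Tr(D G) + e_nuc + E_s.

    Returns dict with mo_coeff, mo_energy, density, energy, n_iter, and the
    converged extra operator (``v_extra``).
    """
    if n_elec % 2 != 0:
        raise ValueError("RHF requires an even electron count")
    nocc = n_elec // 2
    n = S.shape[0]

    s_val, s_vec = eigh(S)
    if s_val.min() < 1e-10:
        raise np.linalg.LinAlgError("overlap matrix is near-singular")
    X = s_vec @ np.diag(s_val**-0.5) @ s_vec.T

    def solve_fock(F):
        e, c = eigh(X.T @ F @ X)
        C = X @ c
        return e, C

    e_mo, C = solve_fock(hcore)
    Cocc = C[:, :nocc]
    D = 2.0 * Cocc @ Cocc.T

    diis_F, diis_err = [], []
    energy = 0.0
    for it in range(1, max_iter + 1):
        v = np.zeros_like(hcore)
        e_fix = 0.0
        if density_term is not None:
            v, e_fix = density_term(D)
        G = fock_2e(eri, D)
        F = hcore + v + G
        err = F @ D @ S - S @ D @ F
        err = X.T @ err @ X
        diis_F.append(F)
        diis_err.append(err)
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.sum(diis_err[i] * diis_err[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:m]
                F = sum(wi * Fi for wi, Fi in zip(w, diis_F))
            except np.linalg.LinAlgError:
                pass
        e_mo, C = solve_fock(F)
        Cocc = C[:, :nocc]
        D_new = 2.0 * Cocc @ Cocc.T
        energy = np.sum(D * hcore) + 0.5 * np.sum(D * G) + e_nuc + e_fix
        derr = np.max(np.abs(D_new - D))
        D = D_new
        if derr < conv_tol and np.max(np.abs(err)) < np.sqrt(conv_tol):
            return {
                "mo_coeff": C, "mo_energy": e_mo, "density": D,
                "energy": energy, "n_iter": it, "v_extra": v,
                "e_extra": e_fix,
            }
    raise SCFConvergenceError(max_iter, float(np.max(np.abs(diis_err[-1]))))
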