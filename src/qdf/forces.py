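"""Analytic nuclear gradients of the frozen-orbital active-space energy.

The electronic energy E = Tr(h gamma) + 1/2 sum g.Gamma + E_nn is evaluated
with RDMs from a converged CASCI (or measured VQE) state over frozen
canonical RHF orbitals.  Differentiating by chain rule gives

  dE/dx = -f_nuc - f_elec                    (Hellmann-Feynman, nuclei/operator)
          + Pulay one- and two-electron integral-derivative terms
          + density-force term  - sum S'_munu W_munu
          + orbital-response term (CPHF),

where W = C sym(X) C^T is the generalized energy-weighted density built
from the generalized Fock X, and the response term accounts for the fact
that the CASCI energy is *not* stationary with respect to core<->active
and occupied<->virtual orbital rotations (it is invariant within the core,
active and virtual blocks, which is what makes the response well defined).
The reported force components change sign so that ``total`` is the force
-dE/dx on each nucleus (Hartree/Bohr).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import integrals as ints
from .core import MolecularIntegrals, ActiveSpaceSpec
from .scf import fock_2e


@dataclass
class ForceDecomposition:
    f_nuc: np.ndarray        # (natom, 3) nuclear Hellmann-Feynman
    f_elec: np.ndarray       # electronic Hellmann-Feynman
    f_density: np.ndarray    # overlap/density force + orbital response
    f_integral: np.ndarray   # Pulay integral force (h and ERI derivatives)
    total: np.ndarray

    def as_dict(self):
        return {k: getattr(self, k).tolist()
                for k in ("f_nuc", "f_elec", "f_density", "f_integral", "total")}


def full_space_rdms(mol: MolecularIntegrals, spec: ActiveSpaceSpec,
                    rdm1_active, rdm2_active):
    """Spin-summed full-MO-space RDMs from active-space RDMs plus the
    closed-shell frozen core."""
    n = mol.n_orb
    froz = list(spec.frozen_set)
    act = list(spec.active_set)
    gamma = np.zeros((n, n))
    for m in froz:
        gamma[m, m] = 2.0
    gamma[np.ix_(act, act)] += rdm1_active

    gI = np.zeros((n, n))
    for m in froz:
        gI[m, m] = 2.0
    gA = np.zeros((n, n))
    gA[np.ix_(act, act)] = rdm1_active

    Gamma = (np.einsum("pq,rs->pqrs", gI, gI)
             - 0.5 * np.einsum("ps,qr->pqrs", gI, gI))
    Gamma += (np.einsum("pq,rs->pqrs", gI, gA)
              + np.einsum("pq,rs->pqrs", gA, gI)
              - 0.5 * np.einsum("ps,qr->pqrs", gI, gA)
              - 0.5 * np.einsum("ps,qr->pqrs", gA, gI))
    Gamma[np.ix_(act, act, act, act)] += rdm2_active
    return gamma, Gamma


def generalized_fock(mol: MolecularIntegrals, gamma, Gamma):
    """X_mp = sum_q h_mq gamma_pq + sum_qrs (mq|rs) Gamma_pqrs (MO basis).

    The orbital gradient of the energy is dE = 2 Tr(U^T X) for C -> C(1+U).
    """
    X = mol.h_core @ gamma
    X += np.einsum("mqrs,pqrs->mp", mol.eri, Gamma, optimize=True)
    return X


def _symmetrize_8fold(T):
    T = 0.5 * (T + T.transpose(1, 0, 2, 3))
    T = 0.5 * (T + T.transpose(0, 1, 3, 2))
    T = 0.5 * (T + T.transpose(2, 3, 0, 1))
    return T


def _cphf_orbital_response(mol, ao, coords, mm_charges=None, mm_centers=None):
    """First-order canonical-orbital rotations U^(x) for each coordinate.

    Returns list of U (MO, full matrix) per (atom, axis) in ``coords``,
    together with the MO overlap derivatives s1.  Solves the coupled-
    perturbed HF equations in the occupied x virtual block.
    """
    C = mol.mo_coeff
    eps = mol.mo_energy
    n = mol.n_orb
    nocc = mol.n_elec // 2
    occ = slice(0, nocc)
    virt = slice(nocc, n)
    D = 2.0 * C[:, occ] @ C[:, occ].T
    eri_mo = mol.eri

    # CPHF response matrix over (virt, occ) pairs:
    # G(dD)_ai with dD from U_ai -> 4(ai|bj) - (ab|ij) - (aj|ib)
    na, ni = n - nocc, nocc
    Amat = np.zeros((na * ni, na * ni))
    for a in range(na):
        for i in range(ni):
            row = a * ni + i
            for b in range(na):
                for j in range(ni):
                    col = b * ni + j
                    Amat[row, col] = (4.0 * eri_mo[nocc + a, i, nocc + b, j]
                                      - eri_mo[nocc + a, nocc + b, i, j]
                                      - eri_mo[nocc + a, j, i, nocc + b])
            Amat[row, row] += eps[nocc + a] - eps[i]

    charges = list(ao["Z"])
    centers = list(ao["centers"])
    if mm_charges is not None and len(mm_charges):
        charges = charges + list(mm_charges)
        centers = centers + list(mm_centers)
    charges = np.asarray(charges, float)
    centers = np.asarray(centers, float)

    out = []
    basis = ao["basis"]
    for atom, axis in coords:
        dS_b = ints.overlap_derivative_bra(basis, atom, axis)
        dS = dS_b + dS_b.T
        dH_b = ints.core_derivative_bra(basis, atom, axis, charges, centers)
        dH = dH_b + dH_b.T
        # operator-center part of the one-electron Hamiltonian derivative
        Zq = ao["Z"][atom]
        dH += -Zq * ints.operator_center_derivative(basis, ao["centers"][atom],
                                                    axis)
        dG1 = ints.eri_derivative_bra(basis, atom, axis)
        dERI = (dG1 + dG1.transpose(1, 0, 2, 3)
                + dG1.transpose(2, 3, 0, 1) + dG1.transpose(3, 2, 1, 0))
        dF_ao = dH + (np.einsum("pqrs,rs->pq", dERI, D, optimize=True)
                      - 0.5 * np.einsum("prqs,rs->pq", dERI, D, optimize=True))
        f1 = C.T @ dF_ao @ C
        s1 = C.T @ dS @ C

        # density change from the occupied-block orthonormality part
        # dD^(s) = -C_occ s1_oo C_occ^T (doubled for closed shell)
        dD_s = -C[:, occ] @ s1[occ, occ] @ C[:, occ].T * 2.0
        f1 = f1 + C.T @ fock_2e(ao["eri"], dD_s) @ C

        # solve for U_virt,occ including its own 2e response
        B = -(f1[virt, occ] - s1[virt, occ] * eps[occ][None, :])
        Uvo = np.linalg.solve(Amat, B.reshape(-1)).reshape(na, ni)

        # total first-order Fock incl. response density
        dD_u = 2.0 * (C[:, virt] @ Uvo @ C[:, occ].T)
        dD_u = dD_u + dD_u.T
        f1_tot = f1 + C.T @ fock_2e(ao["eri"], dD_u) @ C

        U = np.zeros((n, n))
        denom = eps[None, :] - eps[:, None]
        mask = np.abs(denom) > 1e-8
        rhs = f1_tot - s1 * eps[None, :]
        U[mask] = rhs[mask] / denom[mask]
        U[~mask] = 0.0
        np.fill_diagonal(U, -0.5 * np.diag(s1))
        # enforce the occ-virt block from the CPHF solve (exact)
        U[virt, occ] = Uvo
        U[occ, virt] = -s1[occ, virt] - Uvo.T
        out.append((U, s1, dS_b, dH_b, dG1))
    return out


def assemble_forces(mol: MolecularIntegrals, spec: ActiveSpaceSpec,
                    rdm1_active, rdm2_active, ao, *,
                    mm_charges=None, mm_centers=None) -> ForceDecomposition:
    """Nuclear forces of the frozen-orbital active-space energy.

    ``ao`` is the AO-integral context of :func:`qdf.core.ao_integrals` for
    the same geometry (supplies basis functions and derivative machinery).
    MM point charges, when given, are included in the one-electron
    Hamiltonian and the nuclear term exactly as during the energy run.
    """
    natom = len(mol.geometry)
    gamma, Gamma = full_space_rdms(mol, spec, rdm1_active, rdm2_active)
    X = generalized_fock(mol, gamma, Gamma)
    Xs = 0.5 * (X + X.T)
    C = mol.mo_coeff

    # block structure: response only through inter-block rotations
    blocks = np.zeros(mol.n_orb, dtype=int)
    for m in spec.frozen_set:
        blocks[m] = 0
    for a_ in spec.active_set:
        blocks[a_] = 1
    rest = [p for p in range(mol.n_orb)
            if p not in spec.frozen_set and p not in spec.active_set]
    for p in rest:
        blocks[p] = 2

    D_ao = C @ gamma @ C.T
    Gamma_ao = np.einsum("pqrs,mp->mqrs", Gamma, C, optimize=True)
    Gamma_ao = np.einsum("mqrs,nq->mnrs", Gamma_ao, C, optimize=True)
    Gamma_ao = np.einsum("mnrs,lr->mnls", Gamma_ao, C, optimize=True)
    Gamma_ao = np.einsum("mnls,ks->mnlk", Gamma_ao, C, optimize=True)
    Gamma_ao = _symmetrize_8fold(Gamma_ao)
    W = C @ Xs @ C.T

    Zq = ao["Z"]
    centers = ao["centers"]
    charges_all = list(Zq)
    centers_all = [c for c in centers]
    if mm_charges is not None and len(mm_charges):
        charges_all += list(mm_charges)
        centers_all += list(mm_centers)
    charges_all = np.asarray(charges_all, float)
    centers_all = np.asarray(centers_all, float)

    coords = [(a, ax) for a in range(natom) for ax in range(3)]
    resp = _cphf_orbital_response(mol, ao, coords, mm_charges=mm_charges,
                                  mm_centers=mm_centers)

    f_nuc = np.zeros((natom, 3))
    f_elec = np.zeros((natom, 3))
    f_density = np.zeros((natom, 3))
    f_integral = np.zeros((natom, 3))

    for (atom, axis), (U, s1, dS_b, dH_b, dG1) in zip(coords, resp):
        # nuclear Hellmann-Feynman: derivative of nuclear-nuclear (+ MM) energy
        dEnn = 0.0
        for k, (q, c) in enumerate(zip(charges_all, centers_all)):
            if k == atom:
                continue
            r = centers[atom] - c
            dEnn += -Zq[atom] * q * r[axis] / np.linalg.norm(r) ** 3
        f_nuc[atom, axis] = -dEnn

        # electronic Hellmann-Feynman: operator-center derivative
        dV_op = -Zq[atom] * ints.operator_center_derivative(
            ao["basis"], centers[atom], axis)
        f_elec[atom, axis] = -float(np.sum(D_ao * dV_op))

        # Pulay integral force: one-electron (bra+ket) and two-electron
        dE_h = 2.0 * float(np.sum(dH_b * D_ao))
        dE_g = 2.0 * float(np.einsum("mnls,mnls->", dG1, Gamma_ao,
                                     optimize=True))
        f_integral[atom, axis] = -(dE_h + dE_g)

        # density force + orbital response
        dE_s = -2.0 * float(np.sum(dS_b * W))
        A = U + 0.5 * s1
        A[blocks[:, None] == blocks[None, :]] = 0.0
        dE_resp = 2.0 * float(np.sum(A * X))
        f_density[atom, axis] = -(dE_s + dE_resp)

    total = f_nuc + f_elec + f_density + f_integral
    return ForceDecomposition(f_nuc, f_elec, f_density, f_integral, total)
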