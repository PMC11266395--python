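"""Molecular integrals and active-space (frozen-core) Hamiltonians.

The pipeline treats a small electronically interesting window -- by default
the HOMO/LUMO-centered (2e, 2o) space -- with an exact or quantum-emulated
solver, while the remaining doubly occupied orbitals contribute a
mean-field effective potential and core energy.  All tensors are in an
orthonormal restricted-HF molecular-orbital basis, two-electron integrals
in chemists' notation (pq|rs), energies in Hartree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals as ints
from .basis import build_basis
from .fci import fci_ground_state
from .scf import rhf
from .units import BOHR_PER_ANGSTROM, ELEMENT_Z


@dataclass
class MolecularIntegrals:
    """Mean-field molecular integrals in the MO basis."""

    n_orb: int
    n_elec: int
    h_core: np.ndarray       # MO one-electron integrals (includes embedding)
    eri: np.ndarray          # MO (pq|rs), chemists' notation
    e_nuc: float             # nuclear repulsion (+ fixed external scalar terms)
    mo_coeff: np.ndarray
    mo_energy: np.ndarray
    ao_overlap: np.ndarray
    geometry: list           # [(symbol, (x, y, z) Angstrom), ...]
    # AO-level context carried along for solvation / force / embedding work
    ao_hcore: np.ndarray = None
    ao_eri: np.ndarray = None
    basis: list = None
    scf_energy: float = None

    def validate(self, tol=1e-8):
        assert np.allclose(self.h_core, self.h_core.T, atol=tol)
        ortho = self.mo_coeff.T @ self.ao_overlap @ self.mo_coeff
        assert np.allclose(ortho, np.eye(self.n_orb), atol=tol)
        e = self.eri
        for perm in (e.transpose(1, 0, 2, 3), e.transpose(0, 1, 3, 2),
                     e.transpose(2, 3, 0, 1), e.transpose(3, 2, 1, 0)):
            assert np.allclose(e, perm, atol=tol)


@dataclass
class ActiveSpaceSpec:
    """Which spatial orbitals are frozen and which are active."""

    n_active_orb: int
    n_active_elec: int
    frozen_set: list
    active_set: list

    def __post_init__(self):
        if set(self.frozen_set) & set(self.active_set):
            raise ValueError("frozen and active sets overlap")

    @classmethod
    def from_counts(cls, mol: MolecularIntegrals, n_active_elec: int,
                    n_active_orb: int):
        """HOMO/LUMO-centered energy window; ties broken by orbital index."""
        if (mol.n_elec - n_active_elec) % 2:
            raise ValueError("frozen electrons must pair up")
        n_frozen = (mol.n_elec - n_active_elec) // 2
        order = np.argsort(mol.mo_energy, kind="stable")
        occ_sorted = [int(i) for i in order[:mol.n_elec // 2]]
        virt_sorted = [int(i) for i in order[mol.n_elec // 2:]]
        n_act_occ = n_active_elec // 2
        n_act_virt = n_active_orb - n_act_occ
        if n_act_virt < 0 or n_act_virt > len(virt_sorted):
            raise ValueError("active space inconsistent with orbital count")
        frozen = occ_sorted[:n_frozen]
        active = occ_sorted[n_frozen:] + virt_sorted[:n_act_virt]
        return cls(n_active_orb, n_active_elec, frozen, sorted(active))

    def check(self, mol: MolecularIntegrals):
        if 2 * len(self.frozen_set) + self.n_active_elec != mol.n_elec:
            raise ValueError("electron bookkeeping broken")
        if len(self.active_set) != self.n_active_orb:
            raise ValueError("active orbital count mismatch")


@dataclass
class ActiveHamiltonian:
    """Active-space Hamiltonian with the frozen core folded in."""

    h_eff: np.ndarray
    eri_active: np.ndarray
    e_core: float            # mean-field core energy + nuclear repulsion
    n_active_orb: int
    n_active_elec: int


def geometry_centers_bohr(geometry):
    return np.array([xyz for _, xyz in geometry], dtype=float) * BOHR_PER_ANGSTROM


def nuclear_repulsion(geometry):
    centers = geometry_centers_bohr(geometry)
    Z = [ELEMENT_Z[s.capitalize()] for s, _ in geometry]
    e = 0.0
    for i in range(len(Z)):
        for j in range(i):
            e += Z[i] * Z[j] / np.linalg.norm(centers[i] - centers[j])
    return e


def ao_integrals(geometry, basis_name):
    """AO-basis S, T, V_ne, ERI plus geometry bookkeeping."""
    if not geometry:
        raise ValueError("empty geometry")
    basis = build_basis(geometry, basis_name)
    centers = geometry_centers_bohr(geometry)
    Z = np.array([ELEMENT_Z[s.capitalize()] for s, _ in geometry], float)
    S = ints.overlap_matrix(basis)
    T = ints.kinetic_matrix(basis)
    V = ints.nuclear_attraction_matrix(basis, Z, centers)
    eri = ints.eri_tensor(basis)
    return {"basis": basis, "S": S, "T": T, "V": V, "eri": eri,
            "centers": centers, "Z": Z, "e_nuc": nuclear_repulsion(geometry)}


def mo_transform(C, h_ao, eri_ao):
    h = C.T @ h_ao @ C
    eri = np.einsum("pi,pqrs->iqrs", C, eri_ao, optimize=True)
    eri = np.einsum("qj,iqrs->ijrs", C, eri, optimize=True)
    eri = np.einsum("rk,ijrs->ijks", C, eri, optimize=True)
    eri = np.einsum("sl,ijks->ijkl", C, eri, optimize=True)
    return h, eri


def build_integrals(geometry, basis_name, charge=0, spin=0, *,
                    h_extra=None, e_extra=0.0, density_term=None,
                    ao=None) -> MolecularIntegrals:
    """Converged RHF molecular integrals for a geometry.

    ``h_extra`` is an optional fixed AO one-electron operator (MM point
    charge embedding); ``e_extra`` the accompanying scalar (QM-nuclei vs MM
    charges); ``density_term`` a density-dependent operator (reaction
    field) passed through to the SCF.  ``ao`` lets callers reuse
    precomputed AO integrals.
    """
    if spin != 0:
        raise ValueError("only closed-shell (spin=0) references supported")
    if ao is None:
        ao = ao_integrals(geometry, basis_name)
    n_elec = int(ao["Z"].sum()) - charge
    hcore_ao = ao["T"] + ao["V"]
    if h_extra is not None:
        hcore_ao = hcore_ao + h_extra
    res = rhf(ao["S"], hcore_ao, ao["eri"], n_elec, ao["e_nuc"] + e_extra,
              density_term=density_term)
    if density_term is not None:
        hcore_ao = hcore_ao + res["v_extra"]
    h_mo, eri_mo = mo_transform(res["mo_coeff"], hcore_ao, ao["eri"])
    return MolecularIntegrals(
        n_orb=len(ao["basis"]), n_elec=n_elec, h_core=h_mo, eri=eri_mo,
        e_nuc=ao["e_nuc"] + e_extra, mo_coeff=res["mo_coeff"],
        mo_energy=res["mo_energy"], ao_overlap=ao["S"], geometry=list(geometry),
        ao_hcore=hcore_ao, ao_eri=ao["eri"], basis=ao["basis"],
        scf_energy=res["energy"])


def fold_active_space(mol: MolecularIntegrals,
                      spec: ActiveSpaceSpec) -> ActiveHamiltonian:
    """Fold frozen doubly occupied orbitals into an effective potential and
    core energy (closed-shell spatial-orbital form).

    V_eff_pq = sum_m (2 (mm|pq) - (mp|qm)),
    E_core   = 2 sum_m h_mm + sum_mn (2 (mm|nn) - (mn|nm)),
    with m, n over the frozen set; e_core also absorbs nuclear repulsion.
    """
    spec.check(mol)
    act = list(spec.active_set)
    froz = list(spec.frozen_set)
    h = mol.h_core
    eri = mol.eri
    if froz:
        v_eff = (2.0 * np.einsum("mmpq->pq", eri[np.ix_(froz, froz)])
                 - np.einsum("mpqm->pq", eri[froz][:, :, :, froz]))
        e_core = 2.0 * np.einsum("mm->", h[np.ix_(froz, froz)])
        g_ff = eri[np.ix_(froz, froz, froz, froz)]
        e_core += 2.0 * np.einsum("mmnn->", g_ff) - np.einsum("mnnm->", g_ff)
    else:
        v_eff = np.zeros_like(h)
        e_core = 0.0
    h_eff = (h + v_eff)[np.ix_(act, act)]
    eri_active = eri[np.ix_(act, act, act, act)]
    return ActiveHamiltonian(h_eff=h_eff, eri_active=eri_active,
                             e_core=float(e_core + mol.e_nuc),
                             n_active_orb=spec.n_active_orb,
                             n_active_elec=spec.n_active_elec)


def casci_solve(ham: ActiveHamiltonian):
    """Exact ground state of the active-space Hamiltonian.

    Diagonalizes in the Ms=0 determinant basis (dense; intended for <= ~8
    active orbitals) and contracts spin-summed RDMs from the CI vector.
    Returns (energy, ci_vector, rdm1, rdm2); energy includes ``e_core``.
    For a degenerate ground state an arbitrary lowest eigenvector is
    returned; :func:`casci_solve_full` additionally reports the
    degeneracy flag.
    """
    return casci_solve_full(ham)[:4]


def casci_solve_full(ham: ActiveHamiltonian):
    if ham.n_active_orb > 8:
        raise ValueError("dense CASCI limited to 8 active orbitals")
    if ham.n_active_elec % 2:
        raise ValueError("closed-shell sectors only (even electron count)")
    na = nb = ham.n_active_elec // 2
    e_elec, civec, degenerate, space = fci_ground_state(
        ham.h_eff, ham.eri_active, ham.n_active_orb, na, nb)
    rdm1, rdm2 = space.rdm12(civec)
    return float(e_elec + ham.e_core), civec, rdm1, rdm2, degenerate
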