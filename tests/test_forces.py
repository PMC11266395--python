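"""Analytic active-space nuclear gradients against the finite-difference
oracle, plus conservation laws."""

import numpy as np
import pytest

from qdf.core import (ActiveSpaceSpec, ao_integrals, build_integrals,
                      casci_solve_full, fold_active_space)
from qdf.forces import assemble_forces, full_space_rdms, generalized_fock
from qdf.units import ANGSTROM_PER_BOHR

from helpers import H3PLUS_GEOMETRY, WATER_GEOMETRY


def casci_point(geometry, charge=0, basis="sto-3g", nae=2, nao=2):
    ao = ao_integrals(geometry, basis)
    mol = build_integrals(geometry, basis, charge=charge, ao=ao)
    spec = ActiveSpaceSpec.from_counts(mol, nae, nao)
    ham = fold_active_space(mol, spec)
    e, _, r1, r2, _ = casci_solve_full(ham)
    return e, mol, spec, r1, r2, ao


def analytic_forces(geometry, charge=0):
    e, mol, spec, r1, r2, ao = casci_point(geometry, charge)
    return e, assemble_forces(mol, spec, r1, r2, ao)


def fd_force(geometry, atom, axis, charge=0, step=1e-3):
    """5-point central difference of the single-point energy, step in
    Bohr."""
    energies = []
    for k in (-2, -1, 1, 2):
        displaced = [
            (s, tuple(np.asarray(x)
                      + k * step * ANGSTROM_PER_BOHR * (np.arange(3) == axis)
                      * (i == atom)))
            for i, (s, x) in enumerate(geometry)]
        energies.append(casci_point(displaced, charge)[0])
    em2, em1, ep1, ep2 = energies
    return -(em2 - 8 * em1 + 8 * ep1 - ep2) / (12 * step)


def test_orbital_gradient_identity(water):
    """dE = 2 Tr(U^T X) for an infinitesimal orbital rotation with the
    RDMs held fixed -- the defining property of the generalized Fock."""
    mol, spec = water["mol"], water["spec"]
    gamma, Gamma = full_space_rdms(mol, spec, water["rdm1"], water["rdm2"])
    X = generalized_fock(mol, gamma, Gamma)
    ao = water["ao"]
    h_ao = ao["T"] + ao["V"]

    from qdf.core import mo_transform

    def energy_of(C):
        h, g = mo_transform(C, h_ao, ao["eri"])
        return float(np.sum(h * gamma)
                     + 0.5 * np.einsum("pqrs,pqrs->", g, Gamma)
                     + ao["e_nuc"])

    rng = np.random.default_rng(0)
    U = rng.normal(size=X.shape) * 1e-6
    C = mol.mo_coeff
    dE = energy_of(C @ (np.eye(mol.n_orb) + U)) - energy_of(C)
    assert dE == pytest.approx(2.0 * np.sum(U * X), rel=1e-4, abs=1e-14)


def test_h2_force_at_variational_minimum():
    """At the bond length minimizing the full-space (2e,2o) energy the
    analytic force vanishes."""
    def fz(r):
        geom = [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, r))]
        return analytic_forces(geom)[1].total[1, 2]

    lo, hi = 0.68, 0.80
    flo = fz(lo)
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        fmid = fz(mid)
        if np.sign(fmid) == np.sign(flo):
            lo, flo = mid, fmid
        else:
            hi = mid
    assert abs(fz(0.5 * (lo + hi))) < 1e-4


def test_h2_force_matches_finite_difference():
    geom = [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.77))]
    _, F = analytic_forces(geom)
    fd = fd_force(geom, 1, 2)
    assert F.total[1, 2] == pytest.approx(fd, abs=1e-4)
    assert np.allclose(F.total.sum(axis=0), 0.0, atol=1e-6)
    assert np.allclose(F.total, F.f_nuc + F.f_elec + F.f_density
                       + F.f_integral, atol=1e-12)


def test_h3plus_forces_match_finite_difference():
    geom = [("H", (0.02, -0.01, 0.0)), ("H", (0.0, 0.05, 0.93)),
            ("H", (0.0, 0.85, 0.28))]
    _, F = analytic_forces(geom, charge=1)
    for atom, axis in ((0, 2), (1, 1), (2, 0)):
        fd = fd_force(geom, atom, axis, charge=1)
        assert F.total[atom, axis] == pytest.approx(fd, abs=1e-4)
    assert np.allclose(F.total.sum(axis=0), 0.0, atol=1e-6)


def test_water_forces_match_finite_difference(water):
    """Displaced water: the module's primary oracle.  The (2e,2o) energy is
    not orbital-stationary, so this exercises every term including the
    orbital response."""
    geom = [("O", (0.0, 0.02, 0.1273)), ("H", (0.01, 0.7672, -0.4692)),
            ("H", (0.0, -0.7472, -0.4592))]
    _, F = analytic_forces(geom)
    for atom, axis in ((0, 2), (1, 1)):
        fd = fd_force(geom, atom, axis)
        assert F.total[atom, axis] == pytest.approx(fd, abs=1e-4)
    assert np.allclose(F.total.sum(axis=0), 0.0, atol=1e-6)


def test_net_torque_vanishes():
    geom = [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.3, 0.8))]
    _, F = analytic_forces(geom)
    centers = np.array([x for _, x in geom]) / ANGSTROM_PER_BOHR
    torque = np.sum(np.cross(centers, F.total), axis=0)
    assert np.allclose(torque, 0.0, atol=1e-5)


def test_exact_vqe_forces_equal_casci_forces(h2):
    """Measured (exact-mode) RDMs fed through the same force assembly must
    reproduce the CASCI forces."""
    from qdf.mapping import parity_transform
    from qdf.vqe import measure_rdms, solve_ground_state

    mol, spec, ao = h2["mol"], h2["spec"], h2["ao"]
    ham = h2["ham"]
    _, _, r1, r2, _ = casci_solve_full(ham)
    F_casci = assemble_forces(mol, spec, r1, r2, ao)

    qh = parity_transform(ham)
    ansatz, theta, _ = solve_ground_state(qh, 2, 2, n_restarts=3, seed=0)
    rdms = measure_rdms(ansatz, theta, 2, 2)
    F_vqe = assemble_forces(mol, spec, rdms.rdm1, rdms.rdm2, ao)
    assert np.max(np.abs(F_vqe.total - F_casci.total)) < 1e-6


def test_hf_limit_forces(h2):
    """theta = HF point (zero active correlation): forces equal the
    frozen-core mean-field forces computed from the HF RDMs."""
    mol, spec, ao = h2["mol"], h2["spec"], h2["ao"]
    rdm1_hf = np.diag([2.0, 0.0])
    rdm2_hf = np.zeros((2, 2, 2, 2))
    rdm2_hf[0, 0, 0, 0] = 2.0   # closed-shell pair in the active HOMO
    F_hf = assemble_forces(mol, spec, rdm1_hf, rdm2_hf, ao)
    # independent check: finite difference of the RHF energy
    step = 1e-3

    def scf_energy(geometry):
        return build_integrals(geometry, "sto-3g").scf_energy

    energies = []
    for k in (-2, -1, 1, 2):
        geom = [("H", (0.0, 0.0, 0.0)),
                ("H", (0.0, 0.0, 0.74 + k * step * ANGSTROM_PER_BOHR))]
        energies.append(scf_energy(geom))
    em2, em1, ep1, ep2 = energies
    fd = -(em2 - 8 * em1 + 8 * ep1 - ep2) / (12 * step)
    assert F_hf.total[1, 2] == pytest.approx(fd, abs=1e-4)
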