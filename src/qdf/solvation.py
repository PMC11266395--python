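"""Conductor-like continuum solvation (COSMO) coupled to the active space.

The solute sits in a cavity built as a union of atom-centered spheres.  The
conductor boundary condition V_r(s) = -Phi(s) on the cavity surface is
discretized on per-sphere point grids and solved as a dense linear system
for the apparent surface charges; the resulting solvation energy and its
one-electron reaction-field operator are scaled by f(eps) = (eps-1)/eps to
account for a finite solvent permittivity (f -> 1 in the conductor limit).

Coupling to the correlated solver follows a single-pass scheme: the
reaction field is converged at the mean-field level, folded into the
active-space Hamiltonian, the active problem is solved once (CASCI or the
VQE emulator), and the solvation energy is re-evaluated from the measured
one-body density.  A fully self-consistent loop is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals as ints
from .core import (ActiveSpaceSpec, MolecularIntegrals, build_integrals,
                   fold_active_space, casci_solve_full, geometry_centers_bohr,
                   mo_transform, ao_integrals)
from .units import BOHR_PER_ANGSTROM, ELEMENT_Z

# Bondi van der Waals radii (Angstrom)
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclass
class SolventConfig:
    epsilon_s: float = 78.3553          # water
    cavity_radii: dict = None           # per-element radii (Angstrom)
    radii_scale: float = 1.2
    n_points_per_sphere: int = 110
    diagonal_factor: float = 1.0694     # COSMO self-interaction constant

    def __post_init__(self):
        if self.epsilon_s < 1.0:
            raise ValueError("relative permittivity must be >= 1")
        if self.cavity_radii is None:
            self.cavity_radii = dict(VDW_RADII)

    @property
    def f_eps(self):
        return (self.epsilon_s - 1.0) / self.epsilon_s


@dataclass
class SolvationResult:
    surface_charges: np.ndarray
    e_solv: float
    h_solv: np.ndarray
    potential_phi: np.ndarray
    grid: np.ndarray


def fibonacci_sphere(n: int) -> np.ndarray:
    """Nearly uniform unit-sphere point set (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def build_cavity(geometry, config: SolventConfig):
    """Surface grid points (Bohr), per-point areas, for the sphere union.

    Points buried inside another atom's sphere are discarded.
    """
    centers = geometry_centers_bohr(geometry)
    radii = []
    for sym, _ in geometry:
        sym = sym.capitalize()
        if sym not in config.cavity_radii:
            raise ValueError(f"no cavity radius for element {sym!r}")
        radii.append(config.cavity_radii[sym] * config.radii_scale
                     * BOHR_PER_ANGSTROM)
    radii = np.array(radii)
    unit = fibonacci_sphere(config.n_points_per_sphere)
    pts, areas = [], []
    for i, (c, R) in enumerate(zip(centers, radii)):
        sphere = c + R * unit
        keep = np.ones(len(sphere), bool)
        for j, (c2, R2) in enumerate(zip(centers, radii)):
            if j == i:
                continue
            keep &= np.linalg.norm(sphere - c2, axis=1) > R2
        pts.append(sphere[keep])
        areas.append(np.full(keep.sum(), 4.0 * np.pi * R**2
                             / config.n_points_per_sphere))
    return np.concatenate(pts), np.concatenate(areas)


class CosmoSolver:
    """Precomputed cavity discretization + electrostatics for one geometry."""

    def __init__(self, geometry, basis, config: SolventConfig):
        self.config = config
        self.geometry = geometry
        self.grid, self.areas = build_cavity(geometry, config)
        n = len(self.grid)
        d = np.linalg.norm(self.grid[:, None, :] - self.grid[None, :, :],
                           axis=-1)
        np.fill_diagonal(d, 1.0)
        A = 1.0 / d
        np.fill_diagonal(A, config.diagonal_factor
                         * np.sqrt(4.0 * np.pi / self.areas))
        self.A_inv = np.linalg.inv(A)
        self.centers = geometry_centers_bohr(geometry)
        self.Z = np.array([ELEMENT_Z[s.capitalize()] for s, _ in geometry],
                          float)
        # (mu|1/|r-s_k||nu) for every grid point
        self.pot = ints.potential_matrices(basis, self.grid)
        self.phi_nuc = np.einsum(
            "a,ka->k", self.Z,
            1.0 / np.linalg.norm(self.grid[:, None, :]
                                 - self.centers[None, :, :], axis=-1))

    def potential(self, density_ao):
        """In vacuo electrostatic potential Phi at the surface points."""
        return self.phi_nuc - np.einsum("kij,ij->k", self.pot, density_ao)

    def solve(self, density_ao) -> SolvationResult:
        phi = self.potential(density_ao)
        q = -self.A_inv @ phi
        f = self.config.f_eps
        e_solv = 0.5 * f * float(phi @ q)
        h_solv = -f * np.einsum("k,kij->ij", q, self.pot)
        return SolvationResult(surface_charges=f * q, e_solv=e_solv,
                               h_solv=h_solv, potential_phi=phi,
                               grid=self.grid)

    def density_term(self, D):
        res = self.solve(D)
        return res.h_solv, res.e_solv


def solve_reaction_field(density_ao, geometry, basis,
                         config: SolventConfig) -> SolvationResult:
    """One-shot conductor-like solve for a fixed solute density."""
    return CosmoSolver(geometry, basis, config).solve(density_ao)


def density_from_rdm(rdm1_active, mol: MolecularIntegrals,
                     spec: ActiveSpaceSpec):
    """Total AO one-body density: closed-shell frozen core + active RDM
    back-transformed through the MO coefficients."""
    if abs(np.trace(rdm1_active) - spec.n_active_elec) > 1e-6:
        raise ValueError("active 1-RDM trace violates the electron count")
    C = mol.mo_coeff
    Cf = C[:, spec.frozen_set]
    Ca = C[:, spec.active_set]
    D = 2.0 * Cf @ Cf.T + Ca @ rdm1_active @ Ca.T
    return D


def _solve_active(ham, engine, *, plan=None, vqe_seed=0, n_restarts=3):
    """Dispatch the active-space solve; returns (energy, rdm1_active)."""
    if engine == "casci":
        e, _, rdm1, _, _ = casci_solve_full(ham)
        return e, rdm1
    from .mapping import parity_transform
    from .vqe import measure_rdms, solve_ground_state
    qh = parity_transform(ham)
    ansatz, theta, e = solve_ground_state(qh, ham.n_active_orb,
                                          ham.n_active_elec,
                                          n_restarts=n_restarts, seed=vqe_seed)
    if engine == "vqe":
        rdms = measure_rdms(ansatz, theta, ham.n_active_orb,
                            ham.n_active_elec)
        return e, rdms.rdm1
    if engine == "vqe-sampled":
        from .vqe import energy_expectation
        est = energy_expectation(ansatz, theta, qh, plan)
        rdms = measure_rdms(ansatz, theta, ham.n_active_orb,
                            ham.n_active_elec, plan=plan)
        return est.value, rdms.rdm1
    raise ValueError(f"unknown engine {engine!r}")


def solvated_energy_single_pass(geometry, basis_name, n_active_elec,
                                n_active_orb, solvent: SolventConfig,
                                engine="casci", *, iterate=False,
                                conv_tol=1e-6, max_cycles=30, plan=None,
                                vqe_seed=0, ao=None):
    """Active-space energy in solution, single-pass by default.

    The mean-field reaction field is converged self-consistently; the
    correlated (active-space) solve then sees that field once, and the
    final energy re-evaluates the solvation term from the measured 1-RDM:

        E_total = E_active[h + v0] - Tr(D1 v0) + E_s(D1).

    With ``iterate=True`` the reaction field is refreshed from the
    correlated density until the AO density change falls below
    ``conv_tol`` (the fully self-consistent variant).

    Returns (E_total, SolvationResult, diagnostics dict).
    """
    if ao is None:
        ao = ao_integrals(geometry, basis_name)
    solver = CosmoSolver(geometry, ao["basis"], solvent)
    mol = build_integrals(geometry, basis_name, ao=ao,
                          density_term=solver.density_term)
    spec = ActiveSpaceSpec.from_counts(mol, n_active_elec, n_active_orb)
    hcore_gas = ao["T"] + ao["V"]
    C = mol.mo_coeff
    v = mol.ao_hcore - hcore_gas   # converged mean-field reaction field
    diag = {"cycles": 0, "scf_energy": mol.scf_energy}
    e_total = None
    res = None
    D_prev = None
    for cycle in range(max_cycles if iterate else 1):
        h_mo, _ = mo_transform(C, hcore_gas + v, ao["eri"])
        mol_cycle = MolecularIntegrals(
            n_orb=mol.n_orb, n_elec=mol.n_elec, h_core=h_mo, eri=mol.eri,
            e_nuc=mol.e_nuc, mo_coeff=C, mo_energy=mol.mo_energy,
            ao_overlap=mol.ao_overlap, geometry=mol.geometry)
        ham = fold_active_space(mol_cycle, spec)
        e_active, rdm1 = _solve_active(ham, engine, plan=plan,
                                       vqe_seed=vqe_seed)
        D1 = density_from_rdm(rdm1, mol, spec)
        res = solver.solve(D1)
        e_total = e_active - float(np.sum(D1 * v)) + res.e_solv
        diag["cycles"] = cycle + 1
        if D_prev is not None and np.max(np.abs(D1 - D_prev)) < conv_tol:
            break
        D_prev = D1
        v = res.h_solv
    return float(e_total), res, diag
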