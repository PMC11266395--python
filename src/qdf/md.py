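"""Electrostatically embedded QM/MM molecular dynamics.

A small QM region (treated by frozen-core CASCI or its VQE emulation) is
embedded in a bath of MM point charges with Lennard-Jones sites.  The MM
charges enter the QM one-electron Hamiltonian as an external potential;
QM-nuclei/MM-charge Coulomb energy is added as a scalar; MM-MM Coulomb and
all Lennard-Jones interactions are handled classically.  Propagation uses
the BAOAB splitting of Langevin dynamics, which reduces to velocity Verlet
for zero friction and temperature.  QM engines are hot-swappable per step,
emulating a hybrid classical/quantum-processor simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals as ints
from .core import (ActiveSpaceSpec, ao_integrals, build_integrals,
                   fold_active_space, casci_solve_full, geometry_centers_bohr)
from .forces import assemble_forces
from .units import (AMU_TO_AU, ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM,
                    ELEMENT_MASS, ELEMENT_Z, FS_TO_AU, HARTREE_TO_KCALMOL,
                    KB_HARTREE)


@dataclass
class MMEnvironment:
    charges: np.ndarray        # (n,) in e
    positions: np.ndarray      # (n, 3) Angstrom
    lj_epsilon: np.ndarray     # (n,) Hartree
    lj_sigma: np.ndarray       # (n,) Bohr
    masses: np.ndarray         # (n,) amu

    def __post_init__(self):
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.lj_epsilon = np.atleast_1d(np.asarray(self.lj_epsilon, float))
        self.lj_sigma = np.atleast_1d(np.asarray(self.lj_sigma, float))
        self.masses = np.atleast_1d(np.asarray(self.masses, float))

    @property
    def n_sites(self):
        return len(self.charges)


@dataclass
class IntegratorConfig:
    timestep_fs: float = 0.5
    temperature: float = 300.0
    friction_per_ps: float = 1.0
    seed: int = 0
    scheme: str = "baoab"

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.friction_per_ps < 0:
            raise ValueError("friction must be non-negative")


@dataclass
class TrajectoryRecord:
    time_fs: list = field(default_factory=list)
    potential_kcal: list = field(default_factory=list)
    kinetic_kcal: list = field(default_factory=list)
    total_kcal: list = field(default_factory=list)
    qm_energy_hartree: list = field(default_factory=list)
    engine_tags: list = field(default_factory=list)
    bonds_angstrom: dict = field(default_factory=dict)
    angles_deg: dict = field(default_factory=dict)
    positions: list = field(default_factory=list)

    def __len__(self):
        return len(self.time_fs)


def embed_point_charges(basis, mm_charges, mm_centers_bohr, qm_Z,
                        qm_centers_bohr):
    """MM electrostatic contribution to the QM Hamiltonian.

    Returns (h_emb, e_nuc_mm): the AO one-electron operator from the MM
    charges and the scalar QM-nuclei/MM-charge Coulomb energy.
    """
    mm_centers_bohr = np.asarray(mm_centers_bohr, float).reshape(-1, 3)
    mm_charges = np.atleast_1d(np.asarray(mm_charges, float))
    d = np.linalg.norm(qm_centers_bohr[:, None, :] - mm_centers_bohr[None, :, :],
                       axis=-1)
    if d.size and d.min() < 1e-6:
        raise ValueError("MM site coincides with a QM nucleus")
    h_emb = ints.nuclear_attraction_matrix(basis, mm_charges, mm_centers_bohr)
    e_nuc_mm = float(np.einsum("a,k,ak->", qm_Z, mm_charges, 1.0 / d)) \
        if d.size else 0.0
    return h_emb, e_nuc_mm


class QMRegion:
    """QM fragment with an active-space engine and analytic forces."""

    def __init__(self, symbols, basis_name, n_active_elec=2, n_active_orb=2,
                 charge=0, engine="casci", vqe_plan=None, vqe_seed=0):
        self.symbols = list(symbols)
        self.basis_name = basis_name
        self.nae, self.nao = n_active_elec, n_active_orb
        self.charge = charge
        self.engine = engine
        self.vqe_plan = vqe_plan
        self.vqe_seed = vqe_seed
        self.engine_mode = engine
        self.Z = np.array([ELEMENT_Z[s.capitalize()] for s in self.symbols],
                          float)

    def energy_forces(self, positions_ang, mm: MMEnvironment | None,
                      engine=None):
        """QM energy (Hartree) + forces (Hartree/Bohr) on QM atoms and MM
        sites, with MM charges embedded in the Hamiltonian."""
        self.engine_mode = engine or self.engine
        geometry = [(s, tuple(x)) for s, x in zip(self.symbols, positions_ang)]
        ao = ao_integrals(geometry, self.basis_name)
        qm_centers = ao["centers"]
        if mm is not None and mm.n_sites:
            mm_centers = mm.positions * BOHR_PER_ANGSTROM
            h_emb, e_mm = embed_point_charges(ao["basis"], mm.charges,
                                              mm_centers, self.Z, qm_centers)
        else:
            mm_centers = np.zeros((0, 3))
            h_emb, e_mm = None, 0.0
        mol = build_integrals(geometry, self.basis_name, charge=self.charge,
                              ao=ao, h_extra=h_emb, e_extra=e_mm)
        spec = ActiveSpaceSpec.from_counts(mol, self.nae, self.nao)
        ham = fold_active_space(mol, spec)
        rdm1, rdm2, energy = self._solve(ham)
        mm_charges = mm.charges if (mm is not None and mm.n_sites) else None
        F = assemble_forces(mol, spec, rdm1, rdm2, ao,
                            mm_charges=mm_charges,
                            mm_centers=mm_centers if mm_charges is not None
                            else None)
        # forces on MM sites: operator-center derivative + nuclear Coulomb
        f_mm = np.zeros((0, 3))
        if mm_charges is not None:
            D_ao = self._last_density(mol, spec, rdm1)
            f_mm = np.zeros((len(mm_charges), 3))
            for k, (q, c) in enumerate(zip(mm_charges, mm_centers)):
                for axis in range(3):
                    dV = -q * ints.operator_center_derivative(ao["basis"], c,
                                                              axis)
                    dE = float(np.sum(D_ao * dV))
                    r = c - qm_centers
                    dist = np.linalg.norm(r, axis=1)
                    dE += float(np.sum(self.Z * q * (-r[:, axis]) / dist**3))
                    f_mm[k, axis] = -dE
        return energy, F.total, f_mm

    def _solve(self, ham):
        if self.engine_mode == "casci":
            e, _, r1, r2, _ = casci_solve_full(ham)
            return r1, r2, e
        from .mapping import parity_transform
        from .vqe import energy_expectation, measure_rdms, solve_ground_state
        qh = parity_transform(ham)
        ansatz, theta, e = solve_ground_state(qh, ham.n_active_orb,
                                              ham.n_active_elec,
                                              n_restarts=2,
                                              seed=self.vqe_seed)
        plan = self.vqe_plan if self.engine_mode == "vqe-sampled" else None
        if plan is not None:
            e = energy_expectation(ansatz, theta, qh, plan).value
        rdms = measure_rdms(ansatz, theta, ham.n_active_orb,
                            ham.n_active_elec, plan=plan)
        return rdms.rdm1, rdms.rdm2, e

    def _last_density(self, mol, spec, rdm1):
        C = mol.mo_coeff
        Cf = C[:, spec.frozen_set]
        Ca = C[:, spec.active_set]
        return 2.0 * Cf @ Cf.T + Ca @ rdm1 @ Ca.T


def lj_coulomb_energy_forces(positions_bohr, mm: MMEnvironment, n_qm,
                             qm_sigma=None, qm_epsilon=None):
    """Classical MM-MM Coulomb + all-pair Lennard-Jones terms.

    positions_bohr stacks QM atoms first, MM sites after.  Returns
    (energy_hartree, forces_hartree_per_bohr)."""
    n = len(positions_bohr)
    f = np.zeros((n, 3))
    e = 0.0
    sig = np.concatenate([
        qm_sigma if qm_sigma is not None else np.zeros(n_qm), mm.lj_sigma])
    eps = np.concatenate([
        qm_epsilon if qm_epsilon is not None else np.zeros(n_qm),
        mm.lj_epsilon])
    chg = np.concatenate([np.zeros(n_qm), mm.charges])
    for i in range(n):
        for j in range(i + 1, n):
            if i < n_qm and j < n_qm:
                continue  # QM-QM handled quantum mechanically
            r = positions_bohr[i] - positions_bohr[j]
            d = np.linalg.norm(r)
            if i >= n_qm and j >= n_qm and abs(chg[i] * chg[j]) > 0:
                e += chg[i] * chg[j] / d
                fij = chg[i] * chg[j] / d**3 * r
                f[i] += fij
                f[j] -= fij
            eij = np.sqrt(eps[i] * eps[j])
            if eij > 0:
                sij = 0.5 * (sig[i] + sig[j])
                x6 = (sij / d) ** 6
                e += 4 * eij * (x6**2 - x6)
                fmag = 4 * eij * (12 * x6**2 - 6 * x6) / d**2
                fij = fmag * r
                f[i] += fij
                f[j] -= fij
    return e, f


@dataclass
class MDState:
    positions: np.ndarray   # (n, 3) Bohr; QM atoms first
    velocities: np.ndarray  # (n, 3) Bohr / atomic-time
    masses: np.ndarray      # (n,) electron masses


def kinetic_energy(state: MDState) -> float:
    return 0.5 * float(np.sum(state.masses[:, None] * state.velocities**2))


def langevin_step(state: MDState, force_fn, config: IntegratorConfig,
                  forces=None, rng=None):
    """One BAOAB step.  ``force_fn`` maps positions (Bohr) to
    (potential_hartree, forces).  Returns (state, forces, potential)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.timestep_fs * FS_TO_AU
    gamma = config.friction_per_ps / (1000.0 * FS_TO_AU)  # 1/atomic-time
    kT = KB_HARTREE * config.temperature
    m = state.masses[:, None]
    if forces is None:
        _, forces = force_fn(state.positions)
    v = state.velocities + 0.5 * dt * forces / m                 # B
    x = state.positions + 0.5 * dt * v                           # A
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(kT * (1.0 - c1**2))
        v = c1 * v + c2 / np.sqrt(m) * rng.standard_normal(v.shape)  # O
    x = x + 0.5 * dt * v                                         # A
    pot, forces_new = force_fn(x)
    v = v + 0.5 * dt * forces_new / m                            # B
    return MDState(x, v, state.masses), forces_new, pot


@dataclass
class HybridSystem:
    """QM region + MM bath with engine registry for hybrid trajectories."""

    qm: QMRegion
    mm: MMEnvironment
    qm_masses_amu: np.ndarray = None

    def __post_init__(self):
        if self.qm_masses_amu is None:
            self.qm_masses_amu = np.array(
                [ELEMENT_MASS[s.capitalize()] for s in self.qm.symbols])

    def force_fn(self, engine):
        n_qm = len(self.qm.symbols)

        def fn(positions_bohr):
            qm_pos_ang = positions_bohr[:n_qm] * ANGSTROM_PER_BOHR
            mm_now = None
            if self.mm.n_sites:
                mm_now = MMEnvironment(self.mm.charges,
                                       positions_bohr[n_qm:]
                                       * ANGSTROM_PER_BOHR,
                                       self.mm.lj_epsilon, self.mm.lj_sigma,
                                       self.mm.masses)
            e_qm, f_qm, f_mm = self.qm.energy_forces(qm_pos_ang, mm_now,
                                                     engine=engine)
            e_cl, f_cl = lj_coulomb_energy_forces(positions_bohr, self.mm,
                                                  n_qm)
            forces = f_cl.copy()
            forces[:n_qm] += f_qm
            if self.mm.n_sites:
                forces[n_qm:] += f_mm
            fn.last_qm_energy = e_qm
            return e_qm + e_cl, forces

        fn.last_qm_energy = 0.0
        return fn


def run_hybrid_trajectory(system: HybridSystem, qm_positions_ang, schedule,
                          config: IntegratorConfig, *, bonds=None,
                          angles=None, velocities=None,
                          record_positions=False) -> TrajectoryRecord:
    """Propagate with a per-step engine schedule ("classical" -> CASCI,
    "quantum" -> exact VQE emulation, "quantum-sampled" -> shot-based).

    State hands off between engines unchanged, mirroring a simulation
    started on one kind of processor and continued on another.
    """
    engine_of = {"classical": "casci", "quantum": "vqe",
                 "quantum-sampled": "vqe-sampled"}
    n_qm = len(system.qm.symbols)
    pos = np.vstack([np.asarray(qm_positions_ang, float),
                     system.mm.positions]) * BOHR_PER_ANGSTROM
    masses = np.concatenate([system.qm_masses_amu, system.mm.masses]) \
        * AMU_TO_AU
    if velocities is None:
        velocities = np.zeros_like(pos)
    state = MDState(pos, velocities.copy(), masses)
    rng = np.random.default_rng(config.seed)
    record = TrajectoryRecord()
    bonds = bonds or {}
    angles = angles or {}
    for name in bonds:
        record.bonds_angstrom[name] = []
    for name in angles:
        record.angles_deg[name] = []

    forces = None
    for step, tag in enumerate(schedule):
        system.qm.engine_mode = engine_of[tag]
        fn = system.force_fn(engine_of[tag])
        if forces is None:
            pot, forces = fn(state.positions)
        state, forces, pot = langevin_step(state, fn, config, forces=forces,
                                           rng=rng)
        ke = kinetic_energy(state)
        record.time_fs.append((step + 1) * config.timestep_fs)
        record.potential_kcal.append(pot * HARTREE_TO_KCALMOL)
        record.kinetic_kcal.append(ke * HARTREE_TO_KCALMOL)
        record.total_kcal.append((pot + ke) * HARTREE_TO_KCALMOL)
        record.qm_energy_hartree.append(fn.last_qm_energy)
        record.engine_tags.append(tag)
        if record_positions:
            record.positions.append(state.positions.copy())
        for name, (i, j) in bonds.items():
            d = np.linalg.norm(state.positions[i] - state.positions[j])
            record.bonds_angstrom[name].append(d * ANGSTROM_PER_BOHR)
        for name, (i, j, k) in angles.items():
            v1 = state.positions[i] - state.positions[j]
            v2 = state.positions[k] - state.positions[j]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            record.angles_deg[name].append(
                float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
    return record


def monitor_geometry(record: TrajectoryRecord):
    """Per-observable mean/std summary of the monitored bonds and angles."""
    out = {}
    for name, series in record.bonds_angstrom.items():
        arr = np.asarray(series)
        out[f"bond:{name}"] = {"mean": float(arr.mean()),
                               "std": float(arr.std()),
                               "series": arr}
    for name, series in record.angles_deg.items():
        arr = np.asarray(series)
        out[f"angle:{name}"] = {"mean": float(arr.mean()),
                                "std": float(arr.std()),
                                "series": arr}
    return out
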