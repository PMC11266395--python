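"""QM/MM embedding, Langevin integrator and hybrid-engine trajectories."""

import numpy as np
import pytest

from qdf.fixtures import FixtureSpec, toy_solvated_system
from qdf.md import (HybridSystem, IntegratorConfig, MDState, MMEnvironment,
                    QMRegion, kinetic_energy, langevin_step,
                    monitor_geometry, run_hybrid_trajectory)
from qdf.units import ANGSTROM_PER_BOHR, FS_TO_AU, KB_HARTREE

from helpers import H3PLUS_GEOMETRY


def test_zero_charge_bath_is_gas_phase():
    qm = QMRegion(["H", "H", "H"], "sto-3g", charge=1)
    pos = np.array([x for _, x in H3PLUS_GEOMETRY])
    mm = MMEnvironment([0.0, 0.0], [[4.0, 0, 0], [0, 4.0, 0]],
                       [0.0, 0.0], [1.0, 1.0], [1.0, 1.0])
    e_bath, f_bath, _ = qm.energy_forces(pos, mm)
    e_gas, f_gas, _ = qm.energy_forces(pos, None)
    assert e_bath == pytest.approx(e_gas, abs=1e-12)
    assert np.allclose(f_bath, f_gas, atol=1e-12)


def test_point_charge_multipole_limit():
    """Charge Q at 50 Bohr from a +1 QM fragment: interaction -> qQ/d."""
    qm = QMRegion(["H", "H", "H"], "sto-3g", charge=1)
    pos = np.array([x for _, x in H3PLUS_GEOMETRY])
    d = 50.0
    mm = MMEnvironment([0.5], [[d * ANGSTROM_PER_BOHR, 0, 0]],
                       [0.0], [1.0], [1.0])
    e_with, _, _ = qm.energy_forces(pos, mm)
    e_gas, _, _ = qm.energy_forces(pos, None)
    assert (e_with - e_gas) == pytest.approx(0.5 / d, rel=0.01)


def test_coincident_mm_site_rejected():
    from qdf.core import ao_integrals
    from qdf.md import embed_point_charges
    ao = ao_integrals([("H", (0, 0, 0)), ("H", (0, 0, 0.74))], "sto-3g")
    with pytest.raises(ValueError):
        embed_point_charges(ao["basis"], [0.1], ao["centers"][:1],
                            ao["Z"], ao["centers"])


def test_symplectic_limit_energy_conservation():
    """gamma=0, T=0 reduces BAOAB to velocity Verlet: no secular energy
    drift over 10^4 steps at dt = 0.5 fs."""
    k = 0.01

    def ho(x):
        return 0.5 * k * float(np.sum(x**2)), -k * x

    config = IntegratorConfig(timestep_fs=0.5, temperature=0.0,
                              friction_per_ps=0.0)
    state = MDState(np.array([[1.0, 0.0, 0.0]]), np.zeros((1, 3)),
                    np.array([1837.0]))
    rng = np.random.default_rng(0)
    energies = []
    forces = None
    for _ in range(10000):
        state, forces, pot = langevin_step(state, ho, config, forces=forces,
                                           rng=rng)
        energies.append(pot + kinetic_energy(state))
    energies = np.array(energies)
    drift = abs(energies[-500:].mean() - energies[:500].mean()) \
        / abs(energies.mean())
    assert drift < 1e-5


def test_zero_force_uniform_motion():
    def free(x):
        return 0.0, np.zeros_like(x)

    config = IntegratorConfig(timestep_fs=0.5, temperature=0.0,
                              friction_per_ps=0.0)
    v0 = 1e-3
    state = MDState(np.zeros((1, 3)), np.array([[v0, 0.0, 0.0]]),
                    np.array([1837.0]))
    for _ in range(100):
        state, _, _ = langevin_step(state, free, config)
    assert state.positions[0, 0] == pytest.approx(
        v0 * 100 * 0.5 * FS_TO_AU, rel=1e-12)


def test_equipartition_at_300k():
    """Thermostatted harmonic bath: <KE> per degree of freedom = kT/2."""
    k = 0.002

    def ho(x):
        return 0.5 * k * float(np.sum(x**2)), -k * x

    config = IntegratorConfig(timestep_fs=0.5, temperature=300.0,
                              friction_per_ps=50.0, seed=1)
    state = MDState(np.zeros((4, 3)), np.zeros((4, 3)), np.full(4, 1837.0))
    rng = np.random.default_rng(1)
    forces = None
    samples = []
    for step in range(100000):
        state, forces, _ = langevin_step(state, ho, config, forces=forces,
                                         rng=rng)
        if step > 5000:
            samples.append(kinetic_energy(state))
    per_dof = np.mean(samples) / 12.0
    assert per_dof == pytest.approx(0.5 * KB_HARTREE * 300.0, rel=0.03)


def test_momentum_conservation_isolated():
    """gamma=0 isolated pair with internal forces conserves momentum."""
    k = 0.02

    def pair(x):
        r = x[0] - x[1]
        f = -k * r
        return 0.5 * k * float(r @ r), np.array([f, -f])

    config = IntegratorConfig(timestep_fs=0.5, temperature=0.0,
                              friction_per_ps=0.0)
    state = MDState(np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                    np.array([[1e-4, 0, 0], [-5e-5, 0, 0]]),
                    np.array([1837.0, 3674.0]))
    p0 = np.sum(state.masses[:, None] * state.velocities, axis=0)
    for _ in range(2000):
        state, _, _ = langevin_step(state, pair, config)
    p1 = np.sum(state.masses[:, None] * state.velocities, axis=0)
    assert np.allclose(p1, p0, atol=1e-8 * max(1.0, np.linalg.norm(p0)))


@pytest.fixture(scope="module")
def toy_system():
    geometry, mm = toy_solvated_system(
        FixtureSpec(kind="charge_bath", bath_size=8, seed=4), molecule="H2")
    system = HybridSystem(QMRegion([s for s, _ in geometry], "sto-3g"), mm)
    return geometry, system


def test_engine_swap_equivalence(toy_system):
    """All-classical vs all-quantum-exact schedules with the same seed are
    the same trajectory (exact-mode VQE == CASCI)."""
    geometry, system = toy_system
    config = IntegratorConfig(timestep_fs=0.5, temperature=0.0,
                              friction_per_ps=0.0, seed=7)
    qm_pos = [x for _, x in geometry]
    rec_c = run_hybrid_trajectory(system, qm_pos, ["classical"] * 5, config,
                                  bonds={"HH": (0, 1)})
    rec_q = run_hybrid_trajectory(system, qm_pos, ["quantum"] * 5, config,
                                  bonds={"HH": (0, 1)})
    assert np.allclose(rec_c.total_kcal, rec_q.total_kcal, atol=1e-8)
    assert np.allclose(rec_c.qm_energy_hartree, rec_q.qm_energy_hartree,
                       atol=1e-8)
    assert np.allclose(rec_c.bonds_angstrom["HH"], rec_q.bonds_angstrom["HH"],
                       atol=1e-8)


def test_hybrid_handoff_stays_in_envelope(toy_system):
    """classical -> sampled-quantum -> classical hand-off: total energy
    stays within the all-classical envelope widened by 3 sampled-force
    standard deviations."""
    from qdf.vqe import MeasurementPlan
    geometry, system = toy_system
    system.qm.vqe_plan = MeasurementPlan(shots_per_group=8192, seed=3)
    config = IntegratorConfig(timestep_fs=0.5, temperature=0.0,
                              friction_per_ps=0.0, seed=7)
    qm_pos = [x for _, x in geometry]
    n = 9
    schedule = ["classical"] * 3 + ["quantum-sampled"] * 3 + ["classical"] * 3
    rec_c = run_hybrid_trajectory(system, qm_pos, ["classical"] * n, config)
    rec_h = run_hybrid_trajectory(system, qm_pos, schedule, config)
    # sampled-energy scale: sqrt(sum alpha^2 / K) in kcal/mol
    from qdf.core import fold_active_space, ActiveSpaceSpec, build_integrals
    from qdf.mapping import parity_transform
    from qdf.units import HARTREE_TO_KCALMOL
    mol = build_integrals(geometry, "sto-3g")
    qh = parity_transform(fold_active_space(
        mol, ActiveSpaceSpec.from_counts(mol, 2, 2)))
    noise = np.sqrt(np.sum(qh.all_coefficients()**2) / 8192.0) \
        * HARTREE_TO_KCALMOL
    dev = np.max(np.abs(np.array(rec_h.total_kcal)
                        - np.array(rec_c.total_kcal)))
    envelope = (np.max(rec_c.total_kcal) - np.min(rec_c.total_kcal)
                + 3.0 * noise)
    assert dev < envelope
    assert rec_h.engine_tags == schedule


def test_empty_schedule_empty_trajectory(toy_system):
    geometry, system = toy_system
    config = IntegratorConfig(timestep_fs=0.5)
    rec = run_hybrid_trajectory(system, [x for _, x in geometry], [], config)
    assert len(rec) == 0


def test_monitor_frozen_and_harmonic_statistics():
    rec_like = type("R", (), {})()
    from qdf.md import TrajectoryRecord
    rec = TrajectoryRecord()
    rec.bonds_angstrom = {"frozen": [1.86] * 50}
    rec.angles_deg = {}
    out = monitor_geometry(rec)
    assert out["bond:frozen"]["std"] == 0.0
    assert out["bond:frozen"]["mean"] == pytest.approx(1.86)

    # harmonic bond at temperature T: var(r) ~ kT / k_spring
    k_spring = 0.05
    r0 = 2.0

    def bond(x):
        r = x[1] - x[0]
        d = np.linalg.norm(r)
        u = r / d
        f = -k_spring * (d - r0) * u
        return 0.5 * k_spring * (d - r0)**2, np.array([-f, f])

    config = IntegratorConfig(timestep_fs=1.0, temperature=300.0,
                              friction_per_ps=10.0, seed=2)
    state = MDState(np.array([[0.0, 0, 0], [r0, 0, 0]]),
                    np.zeros((2, 3)), np.full(2, 1837.0 * 10))
    rng = np.random.default_rng(2)
    forces = None
    ds = []
    for step in range(80000):
        state, forces, _ = langevin_step(state, bond, config, forces=forces,
                                         rng=rng)
        if step > 8000:
            ds.append(np.linalg.norm(state.positions[1] - state.positions[0]))
    var = np.var(ds)
    assert var == pytest.approx(KB_HARTREE * 300.0 / k_spring, rel=0.10)
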