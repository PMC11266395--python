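"""Ry-ansatz VQE emulator: statevector, expectation, optimization,
sampling, mitigation and RDM measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qdf.core import casci_solve_full
from qdf.mapping import (PauliTerm, QubitHamiltonian, group_commuting,
                         hamiltonian_matrix, parity_transform)
from qdf.vqe import (AnsatzSpec, MeasurementPlan, energy_expectation,
                     expectation_exact, measure_rdms, optimize,
                     parameter_shift_gradient, readout_mitigate,
                     sampled_energy_repeats, simulate_state,
                     solve_ground_state)

from helpers import random_active_hamiltonian


def test_zero_angles_keep_initial_state():
    ansatz = AnsatzSpec(n_qubits=2, n_layers=1, initial_state="00")
    state = simulate_state(ansatz, np.zeros(4))
    assert np.allclose(state, [1, 0, 0, 0])
    ansatz = AnsatzSpec(n_qubits=2, n_layers=1, initial_state="10")
    state = simulate_state(ansatz, np.zeros(4))
    assert np.allclose(state, [0, 0, 1, 0])


def test_single_qubit_ry_closed_form():
    ansatz = AnsatzSpec(n_qubits=1, n_layers=0, initial_state="0")
    state = simulate_state(ansatz, np.array([np.pi / 2]))
    assert state == pytest.approx([np.cos(np.pi / 4), np.sin(np.pi / 4)])


@settings(max_examples=20, deadline=None)
@given(st.lists(st.floats(-np.pi, np.pi), min_size=6, max_size=6))
def test_statevector_real_and_normalized(thetas):
    ansatz = AnsatzSpec(n_qubits=3, n_layers=1, initial_state="101")
    state = simulate_state(ansatz, np.array(thetas)[:6])
    assert state.dtype == np.float64
    assert np.linalg.norm(state) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(3))
def test_exact_expectation_equals_dense_quadratic_form(seed):
    ham = random_active_hamiltonian(2, seed, e_core=0.21)
    qh = parity_transform(ham)
    ansatz = AnsatzSpec.for_active_space(2, 2)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-np.pi, np.pi, ansatz.n_parameters)
    state = simulate_state(ansatz, theta)
    H = hamiltonian_matrix(qh, include_e_core=True)
    dense = float(np.real(state @ H @ state))
    assert expectation_exact(ansatz, theta, qh) == pytest.approx(dense,
                                                                 abs=1e-12)


def test_y_odd_strings_vanish_on_real_states():
    ansatz = AnsatzSpec(n_qubits=2, n_layers=1, initial_state="01")
    theta = np.array([0.3, -1.1, 0.7, 2.2])
    qh = QubitHamiltonian([PauliTerm(1.0, "YI"), PauliTerm(1.0, "YZ"),
                           PauliTerm(1.0, "XY")], 2, 0.0)
    assert expectation_exact(ansatz, theta, qh) == pytest.approx(0.0,
                                                                 abs=1e-12)


def test_minus_z_single_qubit_ground_state():
    qh = QubitHamiltonian([PauliTerm(-1.0, "Z")], 1, 0.0)
    ansatz = AnsatzSpec(n_qubits=1, n_layers=0, initial_state="0")
    _, energy, _ = optimize(ansatz, qh, n_restarts=2, seed=0)
    assert energy == pytest.approx(-1.0, abs=1e-9)


def test_parameter_shift_equals_finite_difference():
    ham = random_active_hamiltonian(2, 7)
    qh = parity_transform(ham)
    ansatz = AnsatzSpec.for_active_space(2, 2)
    rng = np.random.default_rng(1)
    theta = rng.uniform(-np.pi, np.pi, ansatz.n_parameters)
    grad = parameter_shift_gradient(ansatz, theta, qh)
    h = 1e-6
    for i in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        fd = (expectation_exact(ansatz, tp, qh)
              - expectation_exact(ansatz, tm, qh)) / (2 * h)
        assert grad[i] == pytest.approx(fd, abs=1e-7)


@pytest.mark.parametrize("seed", range(10))
def test_single_layer_ansatz_recovers_casci(seed):
    """Exact-mode VQE reaches the CASCI ground energy (expressibility of
    the one-layer Ry circuit on the reduced 2-qubit problem)."""
    ham = random_active_hamiltonian(2, 100 + seed, e_core=0.05 * seed)
    e_cas, _, _, _, _ = casci_solve_full(ham)
    qh = parity_transform(ham)
    _, _, e_vqe = solve_ground_state(qh, 2, 2, n_restarts=5, seed=seed)
    assert e_vqe - e_cas <= 1e-6
    assert e_vqe >= e_cas - 1e-9   # variational bound


def test_shot_noise_scales_inverse_sqrt_k():
    ham = random_active_hamiltonian(2, 5)
    qh = parity_transform(ham)
    ansatz, theta, _ = solve_ground_state(qh, 2, 2, n_restarts=2, seed=0)
    rng = np.random.default_rng(0)
    grouping = group_commuting(qh)
    stds = []
    for K in (2048, 8192, 32768):
        plan = MeasurementPlan(shots_per_group=K, seed=0)
        vals = [energy_expectation(ansatz, theta, qh, plan,
                                   grouping=grouping, rng=rng).value
                for _ in range(50)]
        stds.append(np.std(vals))
    assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.2)
    assert stds[1] / stds[2] == pytest.approx(2.0, rel=0.2)


def test_sampled_variance_matches_coefficient_formula():
    """Reported shot variance agrees with (1/K) sum |alpha_j|^2 within a
    factor of two (grouping only reduces it)."""
    ham = random_active_hamiltonian(2, 9)
    qh = parity_transform(ham)
    ansatz, theta, _ = solve_ground_state(qh, 2, 2, n_restarts=2, seed=0)
    K = 4096
    est = energy_expectation(ansatz, theta, qh,
                             MeasurementPlan(shots_per_group=K, seed=3))
    formula = np.sqrt(np.sum(qh.all_coefficients()**2) / K)
    assert est.std_error <= formula * np.sqrt(2.0)
    assert est.std_error >= formula / np.sqrt(8.0)


def test_readout_mitigation_identity_and_errors():
    hist = np.array([10.0, 20.0, 30.0, 40.0])
    ident = [np.eye(2), np.eye(2)]
    assert np.allclose(readout_mitigate(hist, ident), hist)
    singular = [np.full((2, 2), 0.5), np.eye(2)]
    with pytest.raises(np.linalg.LinAlgError):
        readout_mitigate(hist, singular)
    with pytest.raises(ValueError):
        MeasurementPlan(mitigation=True)


def test_mitigation_removes_readout_bias():
    """Under a known 2% symmetric flip model the mitigated estimator is
    within 2 std errors of truth and strictly less biased than the raw
    one."""
    ham = random_active_hamiltonian(2, 11)
    qh = parity_transform(ham)
    ansatz, theta, e_exact = solve_ground_state(qh, 2, 2, n_restarts=2,
                                                seed=0)
    eps = 0.02
    A = [np.array([[1 - eps, eps], [eps, 1 - eps]]) for _ in range(2)]
    grouping = group_commuting(qh)
    rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
    raw, mit = [], []
    for _ in range(100):
        raw.append(energy_expectation(
            ansatz, theta, qh, MeasurementPlan(8192, A, False, 0),
            grouping=grouping, rng=rng1).value)
    for _ in range(100):
        mit.append(energy_expectation(
            ansatz, theta, qh, MeasurementPlan(8192, A, True, 0),
            grouping=grouping, rng=rng2).value)
    bias_raw = abs(np.mean(raw) - e_exact)
    bias_mit = abs(np.mean(mit) - e_exact)
    stderr = np.std(mit) / np.sqrt(len(mit))
    assert bias_mit < bias_raw
    assert bias_mit < 2 * np.std(mit) + 2 * stderr


def test_rdms_hf_point_and_casci_oracle():
    # HF initial state at theta=0: single determinant, rdm1 = diag(2, 0)
    ansatz = AnsatzSpec.for_active_space(2, 2)
    rdms0 = measure_rdms(ansatz, np.zeros(ansatz.n_parameters), 2, 2)
    assert np.allclose(rdms0.rdm1, np.diag([2.0, 0.0]), atol=1e-12)

    ham = random_active_hamiltonian(2, 13)
    _, _, rdm1_ci, rdm2_ci, _ = casci_solve_full(ham)
    qh = parity_transform(ham)
    ansatz, theta, _ = solve_ground_state(qh, 2, 2, n_restarts=4, seed=2)
    rdms = measure_rdms(ansatz, theta, 2, 2)
    assert np.trace(rdms.rdm1) == pytest.approx(2.0, abs=1e-9)
    assert np.max(np.abs(rdms.rdm1 - rdm1_ci)) < 1e-5
    assert np.max(np.abs(rdms.rdm2 - rdm2_ci)) < 1e-5
    # sampled-mode RDMs converge on the same values
    plan = MeasurementPlan(shots_per_group=1 << 15, seed=0)
    sampled = measure_rdms(ansatz, theta, 2, 2, plan=plan)
    assert np.max(np.abs(sampled.rdm1 - rdm1_ci)) < 0.05


def test_repeat_aggregation_pipeline():
    ham = random_active_hamiltonian(2, 17)
    qh = parity_transform(ham)
    ansatz, theta, e_exact = solve_ground_state(qh, 2, 2, n_restarts=2,
                                                seed=0)
    plan = MeasurementPlan(shots_per_group=8192, seed=5)
    mean, std, vals = sampled_energy_repeats(ansatz, theta, qh, plan,
                                             n_repeats=4)
    assert len(vals) == 4
    assert std >= 0
    assert abs(mean - e_exact) < 5 * max(std, 1e-3)
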