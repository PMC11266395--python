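"""Fermion-to-qubit mapping: spectral equivalence, operator algebra,
term counts and measurement grouping."""

import numpy as np
import pytest
from scipy.linalg import eigvalsh

from qdf.core import fold_active_space, casci_solve_full
from qdf.fci import FCISpace
from qdf.mapping import (COEFF_TRUNCATION, PauliSum, PauliTerm,
                         QubitHamiltonian, annihilation_operator,
                         count_measurable_terms, creation_operator,
                         group_commuting, hamiltonian_matrix,
                         hartree_fock_bitstring, parity_transform,
                         pauli_matrix, qubitwise_commute)

from helpers import (fermionic_hamiltonian_matrix, random_active_hamiltonian)


def _pauli_sum_matrix(op: PauliSum):
    dim = 2 ** op.n
    M = np.zeros((dim, dim), dtype=complex)
    for s, c in op.data.items():
        M += c * pauli_matrix(s)
    return M


@pytest.mark.parametrize("mapping", ["parity", "jordan-wigner"])
@pytest.mark.parametrize("n_orb,seed", [(2, 0), (2, 1), (3, 2)])
def test_full_spectrum_equals_fermionic_oracle(mapping, n_orb, seed):
    ham = random_active_hamiltonian(n_orb, seed)
    qh = parity_transform(ham, two_qubit_reduction=False, mapping=mapping)
    ev_q = np.sort(eigvalsh(hamiltonian_matrix(qh)).real)
    ev_f = np.sort(eigvalsh(fermionic_hamiltonian_matrix(ham)))
    assert np.max(np.abs(ev_q - ev_f)) < 1e-9


@pytest.mark.parametrize("seed", range(3))
def test_reduced_spectrum_is_ms0_sector(seed):
    """Two-qubit-reduced operator + e_core must reproduce every Ms=0
    eigenvalue of the determinant-basis CI matrix."""
    ham = random_active_hamiltonian(2, seed, e_core=0.37)
    qh = parity_transform(ham)
    assert qh.n_qubits == 2
    ev_q = np.sort(eigvalsh(hamiltonian_matrix(qh)).real) + ham.e_core
    space = FCISpace(2, 1, 1)
    Hci = space.hamiltonian(ham.h_eff, ham.eri_active)
    ev_ci = np.sort(eigvalsh(Hci)) + ham.e_core
    assert np.max(np.abs(ev_q - ev_ci)) < 1e-9


def test_ladder_operator_algebra_small_modes():
    """{a_p, a^dag_q} = delta_pq and a_p^2 = 0 for <= 3 modes, verified on
    the mapped matrices."""
    n = 3
    for mapping in ("parity", "jordan-wigner"):
        ops = [(_pauli_sum_matrix(annihilation_operator(j, n, mapping)),
                _pauli_sum_matrix(creation_operator(j, n, mapping)))
               for j in range(n)]
        for p in range(n):
            ap, apd = ops[p]
            assert np.allclose(ap @ ap, 0.0, atol=1e-12)
            for q in range(n):
                aq, aqd = ops[q]
                anti = ap @ aqd + aqd @ ap
                expected = np.eye(2**n) if p == q else np.zeros((2**n,) * 2)
                assert np.allclose(anti, expected, atol=1e-12)


def test_number_operator_idempotent_projectors():
    n = 2
    for j in range(n):
        a = _pauli_sum_matrix(annihilation_operator(j, n, "parity"))
        npq = a.conj().T @ a
        assert np.allclose(npq @ npq, npq, atol=1e-12)


def test_asymmetric_fixture_has_eight_measurable_strings(h3plus):
    qh = parity_transform(h3plus["ham"])
    assert qh.n_qubits == 2
    assert count_measurable_terms(qh) == 8


def test_symmetric_h2_has_fewer_strings(h2):
    qh = parity_transform(h2["ham"])
    assert count_measurable_terms(qh) == 4  # IZ, ZI, ZZ, XX only
    assert count_measurable_terms(qh) < 8


def test_identity_only_hamiltonian_counts_zero():
    qh = QubitHamiltonian(terms=[], n_qubits=2, identity_offset=1.3)
    assert count_measurable_terms(qh) == 0


def test_grouping_is_valid_partition(h3plus):
    qh = parity_transform(h3plus["ham"])
    grouping = group_commuting(qh)
    flat = [t.string for g in grouping.groups for t in g]
    assert sorted(flat) == sorted(t.string for t in qh.terms)
    for terms, basis in zip(grouping.groups, grouping.basis_rotation):
        for t in terms:
            # jointly measurable: every non-identity letter matches the
            # group's per-qubit measurement basis
            for q, ch in enumerate(t.string):
                assert ch == "I" or ch == basis[q]
        for t1 in terms:
            for t2 in terms:
                assert qubitwise_commute(t1.string, t2.string)


def test_all_z_hamiltonian_single_group():
    terms = [PauliTerm(0.5, "ZI"), PauliTerm(0.3, "IZ"), PauliTerm(0.1, "ZZ")]
    qh = QubitHamiltonian(terms=terms, n_qubits=2, identity_offset=0.0)
    assert len(group_commuting(qh).groups) == 1


def test_single_term_single_group():
    qh = QubitHamiltonian(terms=[PauliTerm(1.0, "XY")], n_qubits=2,
                          identity_offset=0.0)
    assert len(group_commuting(qh).groups) == 1


def test_reduction_requires_parity_blocked_order():
    ham = random_active_hamiltonian(2, 0)
    with pytest.raises(ValueError):
        parity_transform(ham, two_qubit_reduction=True,
                         mapping="jordan-wigner")
    with pytest.raises(ValueError):
        parity_transform(ham, two_qubit_reduction=True, n_elec_sector=3)


def test_hartree_fock_bitstring_parity_encoding():
    # (2e,2o): occupations (1,0 | 1,0) -> parities (1,1,0,0); dropping
    # qubits 1 and 3 leaves "10"
    assert hartree_fock_bitstring(2, 2) == "10"
    assert hartree_fock_bitstring(2, 2, two_qubit_reduction=False) == "1100"


def test_truncation_threshold_drops_tiny_terms():
    ham = random_active_hamiltonian(2, 0)
    ham.h_eff = np.diag([1.0, 1.0 + 1e-13])
    ham.eri_active = np.zeros((2, 2, 2, 2))
    qh = parity_transform(ham)
    for t in qh.terms:
        assert abs(t.coefficient) > COEFF_TRUNCATION


def test_jsonl_round_trip(tmp_path, h3plus):
    from qdf.mapping import from_jsonl, to_jsonl
    qh = parity_transform(h3plus["ham"])
    path = tmp_path / "ham.jsonl"
    to_jsonl(qh, path)
    back = from_jsonl(path)
    assert back.n_qubits == qh.n_qubits
    assert back.identity_offset == pytest.approx(qh.identity_offset)
    assert back.e_core == pytest.approx(qh.e_core)
    assert [(t.coefficient, t.string) for t in back.terms] == \
        [(t.coefficient, t.string) for t in qh.terms]
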