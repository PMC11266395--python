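"""Emulated VQE with a hardware-efficient Ry ansatz.

The circuit is k interleaved blocks of a CNOT ladder and per-qubit Ry
rotations applied to an initial computational-basis state,

    |psi(theta)> = [ L_Ry^(k) L_CNOT^(k) ... L_Ry^(1) L_CNOT^(1) ] L_Ry^(0) |phi>,

which keeps all amplitudes real -- the natural ansatz family for molecular
ground states.  Energies and reduced density matrices are evaluated either
exactly (statevector contraction) or from simulated measurement shots with
an optional per-qubit readout-confusion model and linear-inversion
mitigation.  Parameters are pre-optimized classically with L-BFGS-B and
parameter-shift gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .mapping import (MeasurementGrouping, PauliSum, PauliTerm,
                      QubitHamiltonian, group_commuting,
                      hartree_fock_bitstring, map_spin_summed_excitation)


@dataclass
class AnsatzSpec:
    n_qubits: int
    n_layers: int = 1
    initial_state: str = None   # bitstring, e.g. "10"; defaults to |0...0>

    def __post_init__(self):
        if self.initial_state is None:
            self.initial_state = "0" * self.n_qubits
        if len(self.initial_state) != self.n_qubits:
            raise ValueError("initial state length != n_qubits")

    @property
    def n_parameters(self):
        return self.n_qubits * (self.n_layers + 1)

    @classmethod
    def for_active_space(cls, n_active_orb, n_active_elec, n_layers=1):
        bits = hartree_fock_bitstring(n_active_orb, n_active_elec)
        return cls(n_qubits=len(bits), n_layers=n_layers, initial_state=bits)


@dataclass
class MeasurementPlan:
    shots_per_group: int = 8192
    readout_model: list = None   # per-qubit 2x2 column-stochastic matrices
    mitigation: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.shots_per_group < 1:
            raise ValueError("need at least one shot")
        if self.mitigation and self.readout_model is None:
            raise ValueError("mitigation requested without a readout model")
        if self.readout_model is not None:
            for A in self.readout_model:
                A = np.asarray(A)
                if not np.allclose(A.sum(axis=0), 1.0, atol=1e-10):
                    raise ValueError("confusion matrices must be column-stochastic")


@dataclass
class ExpectationEstimate:
    value: float
    std_error: float
    per_group_counts: list = None


@dataclass
class ActiveRDMs:
    rdm1: np.ndarray
    rdm2: np.ndarray


# ---------------------------------------------------------------------------
# statevector simulation
# ---------------------------------------------------------------------------

def _apply_ry(state, qubit, theta, n):
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    psi = state.reshape((2 ** qubit, 2, -1))
    a0 = psi[:, 0, :].copy()
    a1 = psi[:, 1, :].copy()
    psi[:, 0, :] = c * a0 - s * a1
    psi[:, 1, :] = s * a0 + c * a1
    return state


def _apply_cnot(state, control, target, n):
    full = state.reshape([2] * n)
    ctrl1 = [slice(None)] * n
    ctrl1[control] = 1
    sub = full[tuple(ctrl1)]
    axis = target if target < control else target - 1
    full[tuple(ctrl1)] = np.flip(sub, axis=axis)
    return state


def simulate_state(ansatz: AnsatzSpec, theta) -> np.ndarray:
    """Real statevector of the Ry ansatz (qubit 0 = leftmost bit)."""
    theta = np.asarray(theta, dtype=float)
    if theta.size != ansatz.n_parameters:
        raise ValueError("wrong parameter count")
    n = ansatz.n_qubits
    state = np.zeros(2 ** n)
    state[int(ansatz.initial_state, 2)] = 1.0
    th = theta.reshape(ansatz.n_layers + 1, n)
    for q in range(n):
        _apply_ry(state, q, th[0, q], n)
    for l in range(1, ansatz.n_layers + 1):
        # CNOT ladder over neighbor pairs (j, j+1), control on the
        # higher-index qubit so the theta=0 circuit fixes the HF bitstring
        for j in range(n - 2, -1, -1):
            _apply_cnot(state, j + 1, j, n)
        for q in range(n):
            _apply_ry(state, q, th[l, q], n)
    return state


def _apply_pauli_string(string, state):
    """P|psi> for a single Pauli string on a real state; returns
    (real_vector, is_imaginary) where is_imaginary means the true result is
    i * real_vector."""
    n = len(string)
    psi = state.astype(float).copy()
    n_y = 0
    for q, ch in enumerate(string):
        if ch == "I":
            continue
        full = psi.reshape((2 ** q, 2, -1))
        a0 = full[:, 0, :].copy()
        a1 = full[:, 1, :].copy()
        if ch == "X":
            full[:, 0, :], full[:, 1, :] = a1, a0
        elif ch == "Z":
            full[:, 1, :] = -a1
        else:  # Y = i * (lower - raise ... ) : track the global i separately
            n_y += 1
            full[:, 0, :], full[:, 1, :] = -a1, a0
    # each Y contributed i * (|1><0| - |0><1|); fold i^n_y
    phase = 1j ** n_y
    if phase.real:
        return psi * phase.real, False
    return psi * phase.imag, True


def pauli_expectation(string, state):
    vec, imag = _apply_pauli_string(string, state)
    return 0.0 if imag else float(state @ vec)


def expectation_exact(ansatz, theta, qh: QubitHamiltonian) -> float:
    state = simulate_state(ansatz, theta)
    val = qh.identity_offset + qh.e_core
    for t in qh.terms:
        val += t.coefficient * pauli_expectation(t.string, state)
    return float(val)


# ---------------------------------------------------------------------------
# sampled expectation with readout model
# ---------------------------------------------------------------------------

def _rotated_probs(state, basis):
    """Measurement probabilities after rotating each qubit into the given
    product basis (letters over {X, Y, Z})."""
    psi = state.astype(complex).copy()
    H = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
    SdgH = H @ np.diag([1, -1j])
    for q, ch in enumerate(basis):
        if ch == "Z":
            continue
        U = H if ch == "X" else SdgH
        full = psi.reshape((2 ** q, 2, -1))
        a0 = full[:, 0, :].copy()
        a1 = full[:, 1, :].copy()
        full[:, 0, :] = U[0, 0] * a0 + U[0, 1] * a1
        full[:, 1, :] = U[1, 0] * a0 + U[1, 1] * a1
    return np.abs(psi) ** 2


def _readout_transform(probs, readout_model, n):
    A = np.array([[1.0]])
    for q in range(n):
        A = np.kron(A, np.asarray(readout_model[q], float))
    return A @ probs


def readout_mitigate(histogram, readout_model):
    """Linear-inversion readout mitigation on a bitstring histogram.

    Applies the inverse tensor-product confusion matrix, clips negative
    quasi-probabilities to zero and renormalizes.  ``histogram`` is an
    array of counts or frequencies over all 2^n bitstrings.
    """
    histogram = np.asarray(histogram, float)
    n = int(np.log2(len(histogram)))
    Ainv = np.array([[1.0]])
    for q in range(n):
        A = np.asarray(readout_model[q], float)
        if abs(np.linalg.det(A)) < 1e-12:
            raise np.linalg.LinAlgError("singular confusion matrix")
        Ainv = np.kron(Ainv, np.linalg.inv(A))
    out = Ainv @ histogram
    out = np.clip(out, 0.0, None)
    total = out.sum()
    if total > 0:
        out = out * histogram.sum() / total
    return out


def _parity_signs(string, n):
    """(-1)^(number of set bits on the string's support), per bitstring."""
    signs = np.ones(2 ** n)
    for q, ch in enumerate(string):
        if ch == "I":
            continue
        bit = (np.arange(2 ** n) >> (n - 1 - q)) & 1
        signs *= 1.0 - 2.0 * bit
    return signs


def energy_expectation(ansatz, theta, qh: QubitHamiltonian,
                       plan: MeasurementPlan | None = None,
                       grouping: MeasurementGrouping = None,
                       rng=None) -> ExpectationEstimate:
    """<H> for the ansatz state: exact when ``plan`` is None, otherwise
    simulated measurement with K shots per qubit-wise commuting group."""
    if plan is None:
        return ExpectationEstimate(value=expectation_exact(ansatz, theta, qh),
                                   std_error=0.0)
    state = simulate_state(ansatz, theta)
    if grouping is None:
        grouping = group_commuting(qh)
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    n = qh.n_qubits
    K = plan.shots_per_group
    value = qh.identity_offset + qh.e_core
    var = 0.0
    histograms = []
    for terms, basis in zip(grouping.groups, grouping.basis_rotation):
        probs = _rotated_probs(state, basis)
        if plan.readout_model is not None:
            probs = _readout_transform(probs, plan.readout_model, n)
        counts = rng.multinomial(K, np.clip(probs, 0, None) / probs.sum())
        histograms.append(counts)
        freqs = counts.astype(float)
        if plan.mitigation:
            freqs = readout_mitigate(freqs, plan.readout_model)
        freqs = freqs / freqs.sum()
        # weighted sum of term estimates from the shared shots
        y = np.zeros(2 ** n)
        for t in terms:
            y += t.coefficient * _parity_signs(t.string, n)
        mean_y = float(freqs @ y)
        value += mean_y
        var += max(float(freqs @ y**2) - mean_y**2, 0.0) / K
    return ExpectationEstimate(value=float(value), std_error=float(np.sqrt(var)),
                               per_group_counts=histograms)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def parameter_shift_gradient(ansatz, theta, qh):
    """Exact gradient via the parameter-shift rule (+-pi/2 shifts)."""
    theta = np.asarray(theta, float)
    grad = np.zeros_like(theta)
    for i in range(theta.size):
        tp = theta.copy()
        tp[i] += np.pi / 2
        tm = theta.copy()
        tm[i] -= np.pi / 2
        grad[i] = 0.5 * (expectation_exact(ansatz, tp, qh)
                         - expectation_exact(ansatz, tm, qh))
    return grad


def optimize(ansatz, qh, *, theta0=None, n_restarts=1, seed=0,
             gtol=1e-9, maxiter=500):
    """Classical pre-optimization of the ansatz parameters (L-BFGS-B with
    parameter-shift gradients on the exact expectation).

    Returns (theta_star, energy, info).  The energy is variational:
    bounded below by the ground state of ``qh`` (+ e_core).
    """
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(1, n_restarts)):
        if theta0 is not None and trial == 0:
            t0 = np.asarray(theta0, float)
        else:
            t0 = rng.uniform(-np.pi, np.pi, ansatz.n_parameters)
        res = minimize(lambda t: expectation_exact(ansatz, t, qh), t0,
                       jac=lambda t: parameter_shift_gradient(ansatz, t, qh),
                       method="L-BFGS-B",
                       options={"maxiter": maxiter, "gtol": gtol,
                                "ftol": 1e-15})
        if best is None or res.fun < best.fun:
            best = res
    info = {"converged": bool(best.success),
            "grad_norm": float(np.max(np.abs(best.jac)))}
    if not best.success:
        import warnings
        warnings.warn("optimizer exhausted iterations; returning best-so-far")
    return best.x, float(best.fun), info


# ---------------------------------------------------------------------------
# reduced density matrices
# ---------------------------------------------------------------------------

def _hermitian_pauli_parts(op: PauliSum):
    """Split a mapped operator into (real-coefficient string dict); for the
    Hermitian part only -- anti-Hermitian components carry imaginary
    coefficients and vanish on expectation against any state for which the
    operator's physical expectation is real."""
    return {s: c.real for s, c in op.data.items() if abs(c.real) > 1e-12}


def measure_rdms(ansatz, theta, n_active_orb, n_active_elec,
                 plan: MeasurementPlan | None = None,
                 mapping="parity") -> ActiveRDMs:
    """Spin-summed active-space RDMs measured on the optimized circuit.

    Exact mode contracts the statevector; sampled mode estimates every
    required Pauli expectation from shot histograms using the measurement
    plan (one qubit-wise-commuting grouping over all needed strings).
    Conventions match :meth:`qdf.fci.FCISpace.rdm12`.
    """
    no = n_active_orb
    state = simulate_state(ansatz, theta)
    ops1 = {}
    for p in range(no):
        for q in range(no):
            ops1[(p, q)] = map_spin_summed_excitation(
                p, q, no, n_elec_sector=n_active_elec, mapping=mapping)

    needed: dict[str, float] = {}
    exprs1 = {}
    for (p, q), op in ops1.items():
        exprs1[(p, q)] = _hermitian_pauli_parts(op)
        for s in exprs1[(p, q)]:
            needed[s] = 0.0
    exprs2 = {}
    for p in range(no):
        for q in range(no):
            for r in range(no):
                for s_ in range(no):
                    prod = ops1[(p, q)] * ops1[(r, s_)]
                    prod.compress()
                    exprs2[(p, q, r, s_)] = _hermitian_pauli_parts(prod)
                    for s in exprs2[(p, q, r, s_)]:
                        needed[s] = 0.0

    n_qubits = len(next(iter(needed))) if needed else 2 * no - 2
    identity = "I" * n_qubits
    if plan is None:
        for s in needed:
            needed[s] = 1.0 if s == identity else pauli_expectation(s, state)
    else:
        rng = np.random.default_rng(plan.seed + 1)
        strings = [s for s in needed if s != identity]
        fake = QubitHamiltonian(
            terms=[PauliTerm(1.0, s) for s in strings],
            n_qubits=n_qubits, identity_offset=0.0)
        grouping = group_commuting(fake)
        needed[identity] = 1.0
        for terms, basis in zip(grouping.groups, grouping.basis_rotation):
            probs = _rotated_probs(state, basis)
            if plan.readout_model is not None:
                probs = _readout_transform(probs, plan.readout_model, n_qubits)
            counts = rng.multinomial(plan.shots_per_group,
                                     np.clip(probs, 0, None) / probs.sum())
            freqs = counts.astype(float)
            if plan.mitigation:
                freqs = readout_mitigate(freqs, plan.readout_model)
            freqs = freqs / freqs.sum()
            for t in terms:
                needed[t.string] = float(freqs @ _parity_signs(t.string, n_qubits))

    rdm1 = np.zeros((no, no))
    for (p, q), expr in exprs1.items():
        rdm1[p, q] = sum(c * needed[s] for s, c in expr.items())
    rdm1 = 0.5 * (rdm1 + rdm1.T)
    rdm2 = np.zeros((no,) * 4)
    for (p, q, r, s_), expr in exprs2.items():
        val = sum(c * needed[s] for s, c in expr.items())
        if q == r:
            val -= rdm1[p, s_]
        rdm2[p, q, r, s_] = val
    return ActiveRDMs(rdm1=rdm1, rdm2=rdm2)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def solve_ground_state(qh: QubitHamiltonian, n_active_orb, n_active_elec,
                       n_layers=1, n_restarts=3, seed=0):
    """Optimize the Ry ansatz for a mapped active-space Hamiltonian.

    Returns (ansatz, theta_star, energy) with energy including e_core.
    """
    ansatz = AnsatzSpec.for_active_space(n_active_orb, n_active_elec,
                                         n_layers=n_layers)
    theta0 = np.zeros(ansatz.n_parameters)
    theta, energy, _ = optimize(ansatz, qh, theta0=theta0,
                                n_restarts=n_restarts, seed=seed)
    return ansatz, theta, energy


def sampled_energy_repeats(ansatz, theta, qh, plan: MeasurementPlan,
                           n_repeats=4):
    """Repeat the full sampled measurement pipeline and report
    (mean, sample std, list of per-repeat energies)."""
    rng = np.random.default_rng(plan.seed)
    grouping = group_commuting(qh)
    vals = []
    for _ in range(n_repeats):
        est = energy_expectation(ansatz, theta, qh, plan, grouping=grouping,
                                 rng=rng)
        vals.append(est.value)
    vals = np.array(vals)
    std = float(vals.std(ddof=1)) if n_repeats > 1 else 0.0
    return float(vals.mean()), std, vals
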