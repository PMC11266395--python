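"""Fermion-to-qubit mapping and measurement grouping.

Maps the active-space Hamiltonian to a weighted sum of Pauli strings.  The
default route is the parity transformation with blocked spin ordering (all
alpha spin-orbitals, then all beta), which localizes the alpha-parity and
total-parity symmetries on qubits n/2-1 and n-1 so both can be replaced by
their sector eigenvalues ("two-qubit reduction").  Jordan-Wigner is
available as a cross-check mapping.

Pauli strings are python strings over {I, X, Y, Z}; position j is qubit j,
which is the most-significant-first convention used by the statevector
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ActiveHamiltonian

COEFF_TRUNCATION = 1e-10

_MULT = {
    ("I", "I"): (1, "I"), ("I", "X"): (1, "X"), ("I", "Y"): (1, "Y"), ("I", "Z"): (1, "Z"),
    ("X", "I"): (1, "X"), ("Y", "I"): (1, "Y"), ("Z", "I"): (1, "Z"),
    ("X", "X"): (1, "I"), ("Y", "Y"): (1, "I"), ("Z", "Z"): (1, "I"),
    ("X", "Y"): (1j, "Z"), ("Y", "X"): (-1j, "Z"),
    ("Y", "Z"): (1j, "X"), ("Z", "Y"): (-1j, "X"),
    ("Z", "X"): (1j, "Y"), ("X", "Z"): (-1j, "Y"),
}

_PAULI_MATS = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}


@dataclass
class PauliTerm:
    coefficient: float
    string: str


@dataclass
class QubitHamiltonian:
    terms: list          # list[PauliTerm], non-identity strings only
    n_qubits: int
    identity_offset: float
    e_core: float = 0.0

    def all_coefficients(self):
        return np.array([t.coefficient for t in self.terms])


@dataclass
class MeasurementGrouping:
    groups: list         # list[list[PauliTerm]]
    basis_rotation: list  # per group: string over {X, Y, Z} per qubit


def _mul_strings(s1, s2):
    phase = 1 + 0j
    out = []
    for c1, c2 in zip(s1, s2):
        ph, c = _MULT[(c1, c2)]
        phase *= ph
        out.append(c)
    return phase, "".join(out)


class PauliSum:
    """Sparse sum of Pauli strings with complex coefficients."""

    def __init__(self, n_qubits, data=None):
        self.n = n_qubits
        self.data = dict(data or {})

    @classmethod
    def identity(cls, n, coeff=1.0):
        return cls(n, {"I" * n: coeff})

    def add(self, string, coeff):
        self.data[string] = self.data.get(string, 0.0) + coeff
        return self

    def __add__(self, other):
        out = PauliSum(self.n, self.data)
        for s, c in other.data.items():
            out.add(s, c)
        return out

    def __mul__(self, other):
        out = PauliSum(self.n)
        for s1, c1 in self.data.items():
            for s2, c2 in other.data.items():
                ph, s = _mul_strings(s1, s2)
                out.add(s, ph * c1 * c2)
        return out

    def scale(self, x):
        return PauliSum(self.n, {s: c * x for s, c in self.data.items()})

    def compress(self, tol=1e-14):
        self.data = {s: c for s, c in self.data.items() if abs(c) > tol}
        return self


def _single(n, pos_letters):
    s = ["I"] * n
    for pos, letter in pos_letters:
        s[pos] = letter
    return "".join(s)


def annihilation_operator(j, n, mapping="parity"):
    """a_j as a PauliSum over n qubits (spin-orbital j)."""
    out = PauliSum(n)
    if mapping == "jordan-wigner":
        z = [(l, "Z") for l in range(j)]
        out.add(_single(n, z + [(j, "X")]), 0.5)
        out.add(_single(n, z + [(j, "Y")]), 0.5j)
        return out
    if mapping != "parity":
        raise ValueError(f"unknown mapping {mapping!r}")
    xs = [(l, "X") for l in range(j + 1, n)]
    if j == 0:
        out.add(_single(n, [(0, "X")] + xs), 0.5)
        out.add(_single(n, [(0, "Y")] + xs), 0.5j)
    else:
        out.add(_single(n, [(j - 1, "Z"), (j, "X")] + xs), 0.5)
        out.add(_single(n, [(j, "Y")] + xs), 0.5j)
    return out


def creation_operator(j, n, mapping="parity"):
    a = annihilation_operator(j, n, mapping)
    return PauliSum(n, {s: np.conj(c) for s, c in a.data.items()})


def _spin_orbital_hamiltonian(ham: ActiveHamiltonian, mapping):
    """Sum over blocked spin-orbitals of h and chemists'-eri terms."""
    no = ham.n_active_orb
    n = 2 * no
    ops_a = [annihilation_operator(j, n, mapping) for j in range(n)]
    ops_c = [creation_operator(j, n, mapping) for j in range(n)]
    total = PauliSum(n)

    def so(p, sigma):
        return p + sigma * no

    h = ham.h_eff
    eri = ham.eri_active
    for p in range(no):
        for q in range(no):
            if abs(h[p, q]) < 1e-14:
                continue
            for sg in (0, 1):
                total = total + (ops_c[so(p, sg)] * ops_a[so(q, sg)]).scale(h[p, q])
            total.compress()
    for p in range(no):
        for q in range(no):
            for r in range(no):
                for s in range(no):
                    g = eri[p, q, r, s]
                    if abs(g) < 1e-14:
                        continue
                    for sg in (0, 1):
                        for tu in (0, 1):
                            term = ops_c[so(p, sg)] * ops_c[so(r, tu)] \
                                * ops_a[so(s, tu)] * ops_a[so(q, sg)]
                            total = total + term.scale(0.5 * g)
                    total.compress()
    return total.compress()


def parity_transform(ham: ActiveHamiltonian, two_qubit_reduction=True,
                     n_elec_sector=None, mapping="parity") -> QubitHamiltonian:
    """Map an active-space Hamiltonian onto qubits.

    With the reduction enabled (parity mapping only), the alpha-parity
    qubit (position n/2-1) and total-parity qubit (position n-1) are
    replaced by their +-1 eigenvalues for the closed-shell target sector of
    ``n_elec_sector`` electrons (N_alpha = N_beta), and the operator acts
    on n-2 qubits.
    """
    if n_elec_sector is None:
        n_elec_sector = ham.n_active_elec
    total = _spin_orbital_hamiltonian(ham, mapping)
    n = total.n
    if two_qubit_reduction:
        if mapping != "parity":
            raise ValueError("two-qubit reduction requires the parity mapping "
                             "with blocked spin ordering")
        if n_elec_sector % 2:
            raise ValueError("closed-shell sector required (even electrons)")
        n_alpha = n_elec_sector // 2
        z_alpha = (-1.0) ** n_alpha
        z_total = (-1.0) ** n_elec_sector
        q1, q2 = n // 2 - 1, n - 1
        reduced = PauliSum(n - 2)
        for s, c in total.data.items():
            if s[q1] not in "IZ" or s[q2] not in "IZ":
                raise ValueError("operator does not commute with the parity "
                                 "symmetries; wrong ordering?")
            if s[q1] == "Z":
                c = c * z_alpha
            if s[q2] == "Z":
                c = c * z_total
            snew = "".join(ch for i, ch in enumerate(s) if i not in (q1, q2))
            reduced.add(snew, c)
        total = reduced.compress()
        n = n - 2

    identity = "I" * n
    offset = 0.0
    terms = []
    for s, c in sorted(total.data.items()):
        if abs(c.imag) > 1e-10:
            raise ValueError(f"non-Hermitian coefficient for {s}: {c}")
        cr = float(c.real)
        if s == identity:
            offset = cr
        elif abs(cr) > COEFF_TRUNCATION:
            terms.append(PauliTerm(cr, s))
    return QubitHamiltonian(terms=terms, n_qubits=n, identity_offset=offset,
                            e_core=ham.e_core)


def count_measurable_terms(qh: QubitHamiltonian) -> int:
    """Number of non-identity Pauli strings that must be measured."""
    return sum(1 for t in qh.terms if abs(t.coefficient) > COEFF_TRUNCATION)


def qubitwise_commute(s1: str, s2: str) -> bool:
    return all(a == b or a == "I" or b == "I" for a, b in zip(s1, s2))


def group_commuting(qh: QubitHamiltonian) -> MeasurementGrouping:
    """Greedy first-fit partition into qubit-wise commuting groups.

    Terms are processed in descending coefficient magnitude, ties broken by
    lexicographic string order, and placed into the first compatible group.
    """
    ordered = sorted(qh.terms, key=lambda t: (-abs(t.coefficient), t.string))
    groups: list[list[PauliTerm]] = []
    for term in ordered:
        for g in groups:
            if all(qubitwise_commute(term.string, t.string) for t in g):
                g.append(term)
                break
        else:
            groups.append([term])
    rotations = []
    for g in groups:
        basis = []
        for qubit in range(qh.n_qubits):
            letters = {t.string[qubit] for t in g} - {"I"}
            basis.append(letters.pop() if letters else "Z")
        rotations.append("".join(basis))
    return MeasurementGrouping(groups=groups, basis_rotation=rotations)


def reduce_pauli_sum(total: PauliSum, n_elec_sector: int) -> PauliSum:
    """Apply the two-qubit parity reduction to any number- and
    spin-parity-conserving operator (blocked ordering)."""
    n = total.n
    if n_elec_sector % 2:
        raise ValueError("closed-shell sector required")
    z_alpha = (-1.0) ** (n_elec_sector // 2)
    z_total = (-1.0) ** n_elec_sector
    q1, q2 = n // 2 - 1, n - 1
    reduced = PauliSum(n - 2)
    for s, c in total.data.items():
        if s[q1] not in "IZ" or s[q2] not in "IZ":
            raise ValueError("operator does not respect the parity symmetries")
        if s[q1] == "Z":
            c = c * z_alpha
        if s[q2] == "Z":
            c = c * z_total
        reduced.add("".join(ch for i, ch in enumerate(s) if i not in (q1, q2)), c)
    return reduced.compress()


def map_spin_summed_excitation(p: int, q: int, n_active_orb: int,
                               two_qubit_reduction=True, n_elec_sector=None,
                               mapping="parity") -> PauliSum:
    """Qubit representation of E_pq = sum_sigma a^dag_p,sigma a_q,sigma."""
    n = 2 * n_active_orb
    total = PauliSum(n)
    for sg in (0, 1):
        i, j = p + sg * n_active_orb, q + sg * n_active_orb
        total = total + (creation_operator(i, n, mapping)
                         * annihilation_operator(j, n, mapping))
    total.compress()
    if two_qubit_reduction:
        if n_elec_sector is None:
            raise ValueError("n_elec_sector required for the reduction")
        total = reduce_pauli_sum(total, n_elec_sector)
    return total


# ---------------------------------------------------------------------------
# dense utilities (tests, exact expectation, tiny systems)
# ---------------------------------------------------------------------------

def pauli_matrix(string: str) -> np.ndarray:
    out = np.array([[1.0 + 0j]])
    for ch in string:
        out = np.kron(out, _PAULI_MATS[ch])
    return out


def hamiltonian_matrix(qh: QubitHamiltonian, include_e_core=False) -> np.ndarray:
    dim = 2 ** qh.n_qubits
    H = np.eye(dim, dtype=complex) * qh.identity_offset
    for t in qh.terms:
        H += t.coefficient * pauli_matrix(t.string)
    if include_e_core:
        H += np.eye(dim) * qh.e_core
    return H


def hartree_fock_bitstring(n_active_orb: int, n_elec: int,
                           two_qubit_reduction=True) -> str:
    """HF reference determinant encoded in the parity basis (blocked spin
    ordering), optionally with the two parity qubits removed."""
    if n_elec % 2:
        raise ValueError("closed-shell sectors only")
    na = n_elec // 2
    occ = [1 if i < na else 0 for i in range(n_active_orb)] * 2
    parity = np.cumsum(occ) % 2
    n = 2 * n_active_orb
    keep = [i for i in range(n) if not (two_qubit_reduction and
                                        i in (n // 2 - 1, n - 1))]
    return "".join(str(int(parity[i])) for i in keep)


def to_jsonl(qh: QubitHamiltonian, path):
    import json
    with open(path, "w") as fh:
        fh.write(json.dumps({"n_qubits": qh.n_qubits,
                             "identity_offset": qh.identity_offset,
                             "e_core": qh.e_core}) + "\n")
        for t in qh.terms:
            fh.write(json.dumps({"coeff": t.coefficient, "string": t.string}) + "\n")


def from_jsonl(path) -> QubitHamiltonian:
    import json
    with open(path) as fh:
        lines = [json.loads(l) for l in fh if l.strip()]
    head = lines[0]
    terms = [PauliTerm(d["coeff"], d["string"]) for d in lines[1:]]
    return QubitHamiltonian(terms=terms, n_qubits=head["n_qubits"],
                            identity_offset=head["identity_offset"],
                            e_core=head.get("e_core", 0.0))
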