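# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the order the pipeline runs.

## Electronic structure layer

The package carries its own electronic-structure stack, sized for the
few-atom QM regions the pipeline targets.

* **Integrals.** Contracted Cartesian Gaussians evaluated by
  McMurchie–Davidson Hermite expansion; the Boys function comes from the
  regularized incomplete gamma function with a stable downward recursion
  for the auxiliary orders. Center derivatives use the exact raise/lower
  identity d/dA φ(i) = 2a φ(i+1) − i φ(i−1), so all force integrals are
  analytic. Embedded basis data: STO-3G (H, C, N, O) and 6-31G (H) —
  the standard Pople parameters. The engine is validated against the
  classic minimal-basis H2 integral tables (all six integral classes to
  the printed precision), against grid quadrature for high angular
  momenta, and against finite differences for every derivative class.
  Larger Pople sets (6-311G(d,p) etc.) are not bundled; analyses that
  would need them run here on the bundled sets instead.
* **SCF.** Closed-shell RHF with DIIS (density and commutator
  convergence, 1e-10). Open-shell references are rejected.
* **Active space.** The default window is HOMO/LUMO-centered: the highest
  n_elec_active/2 occupied and lowest n_orb_active − n_elec_active/2
  virtual canonical orbitals, energy-ordered with ties broken by orbital
  index. Folding uses the spatial-orbital closed-shell forms of the
  effective potential and core energy; the spin-orbital second-quantized
  Hamiltonian keeps the conventional 1/2 on the two-electron term.
  Chemists' notation [pq|rs] is the single in-memory and on-disk (FCIDUMP)
  convention.
* **CASCI.** Dense diagonalization in the Ms = 0 determinant basis
  (α/β occupation strings, spin-summed excitation operators), limited to
  8 active orbitals. RDM conventions: rdm1[p,q] = ⟨E_pq⟩,
  rdm2[p,q,r,s] = ⟨E_pq E_rs⟩ − δ_qr ⟨E_ps⟩, so
  E = Σ h·rdm1 + ½ Σ [pq|rs]·rdm2. Degenerate ground states return an
  arbitrary lowest eigenvector with a flag.

## Qubit mapping

The parity transformation is implemented exactly in its ladder-operator
form, a_j = ½(X_j Z_{j−1} + iY_j) ⊗ X_{j+1..N−1}, over blocked
spin-orbitals (all α, then all β; qubit j ↔ spin-orbital j). In this
encoding qubit N/2−1 carries the α-occupation parity and qubit N−1 the
total parity; for a fixed closed-shell sector (N_α = N_β) both are
replaced by eigenvalues (−1)^{N_α}, (−1)^{N_elec} and removed. Coefficients
below 1e-10 Hartree are truncated (far below chemical relevance, far above
accumulated float noise). Jordan–Wigner is available as a cross-check
mapping; spectra of both agree with brute-force Fock-space matrices to
machine precision in the test suite.

Measurement grouping is by qubit-wise commutation with greedy first-fit:
terms in descending |α_j|, ties lexicographic. A generic asymmetric
(2e, 2o) Hamiltonian has exactly 8 measurable strings
{IZ, ZI, ZZ, XX, XI, IX, XZ, ZX}; under this grouping they always fall
into 4 groups (enumeration over all processing orders confirms 4 is the
only possible first-fit outcome for this set). Reports of five groups for
the same 8-string count correspond to a different Pauli frame or grouping
heuristic; four settings is the better schedule, so the optimum is kept.

## VQE emulation

* **Ansatz.** |ψ(θ)⟩ = [Π_{l=k..1} L_Ry^{(l)} L_CNOT^{(l)}] L_Ry^{(0)}|φ⟩,
  k = 1 by default, parameters θ ∈ R^{N(k+1)}. The CNOT ladder runs over
  neighbor pairs (j, j+1) with the control on the higher-index qubit — the
  convention under which the θ = 0 circuit fixes the parity-encoded
  Hartree–Fock bitstring, which is also the default initial state |φ⟩.
  All amplitudes stay real; Y-odd strings have identically zero
  expectation (asserted in tests).
* **Optimization.** L-BFGS-B on the exact expectation with parameter-shift
  gradients (±π/2 shifts, exact for Ry generators), tight tolerances
  (gtol 1e-9, ftol 1e-15), optional random restarts. On every (2e, 2o)
  fixture the single-layer ansatz reaches the CASCI energy to 1e-6
  Hartree; the variational bound E(θ*) ≥ E_CASCI is asserted.
* **Sampling.** Per group: rotate to the product measurement basis
  (H for X, S†H for Y), draw K multinomial shots (default 8192), push the
  probabilities through per-qubit column-stochastic confusion matrices,
  optionally invert them (clipping negative quasi-probabilities and
  renormalizing), and sum coefficient-weighted parities. The reported
  standard error is the empirical per-group variance of the weighted
  parity observable over K; it matches the (1/K) Σ|α_j|² scaling within
  the grouping gain. Repeated-experiment aggregation (default R = 4)
  reports mean ± sample std (ddof = 1).
* **RDMs.** Every spin-summed excitation operator E_pq and product
  E_pq E_rs is pushed through the same mapping and reduction; exact mode
  contracts the statevector, sampled mode estimates each required Pauli
  string from a dedicated qubit-wise grouping. For (2e, 2o) the 1-RDM
  needs three expectation values beyond the energy measurement.

## Continuum solvation

COSMO with a cavity of atom-centered spheres (Bondi radii × 1.2,
overridable), each discretized by a golden-spiral point set (110
points/sphere default; buried points discarded). The conductor system
A q = −Φ uses A_kl = 1/|s_k − s_l| off-diagonal and the standard
self-interaction diagonal 1.0694·√(4π/a_k). Energy and reaction-field
operator scale with f(ε) = (ε−1)/ε (water default ε = 78.3553); the Born
closed form for a centered charge is reproduced to well under 1% at 302
points. The correlated coupling is single-pass: solvated RHF → fold the
converged mean-field reaction field v0 into h → one active-space solve →
E_total = E_active[h + v0] − Tr(D₁v0) + E_s(D₁) with D₁ from the measured
1-RDM. `iterate=True` refreshes v from D₁ to the fixed point (AO-density
change < 1e-6); on the test systems the difference from single-pass is
~1e-11 Hartree, orders of magnitude below 8192-shot noise, which is why
single-pass is the default. ε = 1 recovers the gas phase exactly.
Nonelectrostatic (cavitation/dispersion) terms and other PCM variants are
out of scope.

## Analytic forces

The frozen-orbital active-space energy is not stationary in the orbital
coefficients, so the gradient has five pieces, all assembled from the
measured RDMs in the AO basis:

1. nuclear Hellmann–Feynman (point charges included),
2. electronic Hellmann–Feynman via operator-center derivatives of the
   nuclear-attraction kernel,
3. Pulay one- and two-electron integral-derivative terms, contracted with
   the total density and the 8-fold-symmetrized full-space 2-RDM
   (core-core, core-active and active-active blocks),
4. the density force −Σ S′_μν W_μν with W = C·sym(X)·Cᵀ, where
   X_mp = (hγ)_mp + Σ [mq|rs] Γ_pqrs is the generalized Fock (the identity
   dE = 2 Tr(UᵀX) for orbital rotations is itself unit-tested),
5. an orbital-response term 2 Tr(AᵀX) with the antisymmetric rotation A
   from coupled-perturbed HF: the occupied-virtual block solves the CPHF
   linear system (with the two-electron response of the perturbed
   density), the remaining blocks follow from first-order canonical
   perturbation theory. Because the CASCI energy is invariant to rotations
   within the core, active and virtual blocks, A is zeroed there — which
   also removes the near-degeneracy sensitivity of those denominators.

The complete gradient matches 5-point finite differences (step 1e-3 Bohr)
to better than 1e-4 Hartree/Bohr on H2, distorted H3+ and distorted water,
with net force < 1e-6 and net torque < 1e-5 on isolated molecules. The
measurement-grouping optimization for a combined "force operator" is
deliberately not implemented. Units are Hartree/Bohr internally.

## QM/MM dynamics

Electrostatic embedding: MM charges add −Σ_c q_c (μ|1/|r−R_c||ν) to the
one-electron Hamiltonian plus the scalar nuclear-charge Coulomb term;
forces on MM sites come from the operator-center derivative (translational
invariance: ∂C = −∂A − ∂B). MM-MM Coulomb and all Lennard-Jones pairs are
classical; QM-QM interactions stay quantum. No covalent QM/MM cuts occur
in the toy systems, so no link atoms are needed.

The integrator is BAOAB Langevin (dt = 0.5 fs, γ = 1/ps, T = 300 K
defaults); γ = T = 0 reduces exactly to velocity Verlet (no secular energy
drift over 10⁴ steps; equipartition holds to 3% on a thermostatted bath).
Engines swap per step from a schedule (classical CASCI, exact-emulation
VQE, shot-sampled VQE) with bitwise state hand-off; exact-mode hybrid
trajectories are identical to classical ones to 1e-8, and sampled segments
stay inside the classical envelope widened by three sampled-force standard
deviations. Test trajectories use order-10 steps and 8–10-site baths;
longer runs (e.g. the 1600-step sanity length) scale linearly at roughly
0.3 s/step for H2 in a 10-charge bath on one CPU.

## Resource estimation and profiles

The pUCCD arithmetic is exact integer/ratio arithmetic: qubits = N,
Givens-SWAP gates = (N_elec/2)(N − N_elec/2), M = round(0.7 N²),
K = (M/groups)·|α|²/ε², wall time = total shots × reset time (1 ms
default). The basis-function table (6-31G: H 2, C/N/O 9, S 13; STO-3G
analogues) is frozen data; new elements mean regenerating the table, not
code changes. Total shots are reported as the exact product
groups × K.

Reaction profiles: ΔG‡ = G(TS) − ΣG(reactants),
ΔG = ΣG(products) − ΣG(reactants), Hartree → kcal/mol via 627.5095.
Sampled-VQE species enter as the mean of their repeats with ddof-1 std;
profile uncertainties are root-sum-square over the species involved
(independent-Gaussian assumption). Each bundled benchmark energy is
treated as a complete Gibbs energy (thermal corrections already applied at
the mean-field level). The default stoichiometry of the bundled prodrug
benchmark is 4 → TS → 5 + 6 + H2O, fixed by exact numerical consistency
of the published per-species energies with the published barriers, and
overridable. Barriers < 20 kcal/mol (strict) are labelled physiologically
accessible; negative barriers are flagged non-physical (sampling noise).

## Synthetic fixtures: what they do and do not show

`fixtures.random_active_integrals` draws a symmetric h and a
positive-semidefinite, 8-fold-symmetric two-electron tensor — a valid
abstract closed-shell Hamiltonian with generic (point-group-free)
structure; the asymmetric mode guarantees |h_pq| ≥ 0.05 off-diagonal so
the full 8-string qubit Hamiltonian is realized. `toy_solvated_system`
surrounds H2 (or water) with a neutral random charge bath (default 10
sites at 3–6 Å, |q| ≤ 0.25 e, weak LJ spheres, water-like masses).

These fixtures exercise every code path — mapping, measurement, solvation
coupling, forces, hybrid hand-off — under controlled conditions, but they
are not a protein: real force fields impose structured charges, bonded
terms and bulk solvent, and real devices add gate noise and drift that the
readout-only error model does not represent. Passing tests therefore
demonstrate correctness of the algorithms and their couplings, not
hardware-level accuracy on biomolecular systems.

## Known limitations

* Bases are limited to the embedded STO-3G/6-31G(H) data; heavy-atom
  split-valence chemistry and the published absolute solvated energies of
  the drug molecules are outside desk scale here.
* Open-shell references, CPHF-free approximations to gradients, SMD-type
  nonelectrostatic solvation, PME/periodic MD and link-atom boundaries are
  not implemented.
* The dense CASCI/Fock-space oracles cap fixture sizes at 6–8 orbitals by
  design.
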