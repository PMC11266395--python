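"""Synthetic, download-free test systems.

Everything the pipeline needs for testing is generated programmatically:
random symmetric active-space integral sets (with the full 8-fold
permutational symmetry and a positive-semidefinite Coulomb tensor), toy
molecules, and neutral point-charge baths with Lennard-Jones sites that
stand in for a protein/solvent MM environment around a small QM region.
All fixtures are reproducible from (kind, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ActiveHamiltonian
from .md import MMEnvironment


@dataclass
class FixtureSpec:
    kind: str = "random_integrals"      # random_integrals | toy_molecule | charge_bath
    n_orb: int = 2
    n_elec: int = 2
    symmetric: bool = False
    seed: int = 0
    bath_size: int = 10
    bath_radius_min: float = 3.0        # Angstrom
    bath_radius_max: float = 6.0        # Angstrom
    charge_scale: float = 0.25          # e
    e_core: float = 0.0


def random_active_integrals(spec: FixtureSpec) -> ActiveHamiltonian:
    """Random active-space Hamiltonian fixture.

    The one-electron part is symmetric; the two-electron tensor is built
    as a Gram matrix over orbital pairs (positive semidefinite, like a
    true Coulomb metric) and symmetrized to the full 8-fold symmetry.  In
    asymmetric mode all one-electron off-diagonals are guaranteed nonzero,
    which realizes the generic 8-term (2e, 2o) qubit Hamiltonian; in
    symmetric mode orbitals are split into two mock irreps and
    symmetry-forbidden one-electron elements are zeroed.
    """
    if spec.n_orb > 6:
        raise ValueError("fixtures limited to 6 orbitals")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_orb
    h = rng.normal(size=(n, n))
    h = 0.5 * (h + h.T)
    if not spec.symmetric:
        for i in range(n):
            for j in range(i + 1, n):
                if abs(h[i, j]) < 0.05:
                    bump = 0.1 if rng.random() < 0.5 else -0.1
                    h[i, j] = h[j, i] = h[i, j] + bump
    M = rng.normal(size=(n * n, n * n)) * 0.3
    eri = (M @ M.T).reshape(n, n, n, n)
    eri = 0.5 * (eri + eri.transpose(1, 0, 2, 3))
    eri = 0.5 * (eri + eri.transpose(0, 1, 3, 2))
    eri = 0.5 * (eri + eri.transpose(2, 3, 0, 1))
    if spec.symmetric:
        irrep = np.array([i % 2 for i in range(n)])
        mask = irrep[:, None] != irrep[None, :]
        h[mask] = 0.0
        for p in range(n):
            for q in range(n):
                for r in range(n):
                    for s in range(n):
                        if (irrep[p] + irrep[q] + irrep[r] + irrep[s]) % 2:
                            eri[p, q, r, s] = 0.0
    return ActiveHamiltonian(h_eff=h, eri_active=eri, e_core=spec.e_core,
                             n_active_orb=n, n_active_elec=spec.n_elec)


TOY_GEOMETRIES = {
    "H2": [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.74))],
    "H2O": [("O", (0.0, 0.0, 0.1173)), ("H", (0.0, 0.7572, -0.4692)),
            ("H", (0.0, -0.7572, -0.4692))],
    "H3+": [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.95)),
            ("H", (0.0, 0.83, 0.31))],
}


def toy_molecule(name="H2"):
    if name not in TOY_GEOMETRIES:
        raise ValueError(f"unknown toy molecule {name!r}")
    return [(s, tuple(x)) for s, x in TOY_GEOMETRIES[name]]


def toy_solvated_system(spec: FixtureSpec, molecule="H2"):
    """QM geometry + neutral MM point-charge bath around it.

    Bath sites are placed on random directions at radii in
    [bath_radius_min, bath_radius_max] Angstrom from the QM centroid
    (outside the QM cavity), charges drawn uniformly and shifted to exact
    overall neutrality; every site carries a weak Lennard-Jones sphere and
    a water-like mass.
    """
    geometry = [(s, tuple(x)) for s, x in TOY_GEOMETRIES[molecule]]
    rng = np.random.default_rng(spec.seed)
    nb = spec.bath_size
    if nb == 0:
        mm = MMEnvironment(np.zeros(0), np.zeros((0, 3)), np.zeros(0),
                           np.zeros(0), np.zeros(0))
        return geometry, mm
    center = np.mean([x for _, x in geometry], axis=0)
    dirs = rng.normal(size=(nb, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = rng.uniform(spec.bath_radius_min, spec.bath_radius_max, (nb, 1))
    pos = center + dirs * radii
    q = rng.uniform(-spec.charge_scale, spec.charge_scale, nb)
    q -= q.mean()
    mm = MMEnvironment(
        charges=q, positions=pos,
        lj_epsilon=np.full(nb, 2e-4), lj_sigma=np.full(nb, 5.0),
        masses=np.full(nb, 18.0))
    return geometry, mm
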