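import numpy as np
import pytest

from qdf.core import (ActiveSpaceSpec, ao_integrals, build_integrals,
                      casci_solve_full, fold_active_space)

from helpers import H3PLUS_GEOMETRY, WATER_GEOMETRY


@pytest.fixture(scope="session")
def water():
    """Water/STO-3G mean field + (2e,2o) CASCI, shared across the suite."""
    ao = ao_integrals(WATER_GEOMETRY, "sto-3g")
    mol = build_integrals(WATER_GEOMETRY, "sto-3g", ao=ao)
    spec = ActiveSpaceSpec.from_counts(mol, 2, 2)
    ham = fold_active_space(mol, spec)
    energy, civec, rdm1, rdm2, degenerate = casci_solve_full(ham)
    return {"geometry": WATER_GEOMETRY, "ao": ao, "mol": mol, "spec": spec,
            "ham": ham, "e_casci": energy, "rdm1": rdm1, "rdm2": rdm2}


@pytest.fixture(scope="session")
def h3plus():
    """Scalene H3+ / STO-3G: the smallest asymmetric closed-shell molecule."""
    ao = ao_integrals(H3PLUS_GEOMETRY, "sto-3g")
    mol = build_integrals(H3PLUS_GEOMETRY, "sto-3g", charge=1, ao=ao)
    spec = ActiveSpaceSpec.from_counts(mol, 2, 2)
    ham = fold_active_space(mol, spec)
    return {"geometry": H3PLUS_GEOMETRY, "ao": ao, "mol": mol, "spec": spec,
            "ham": ham}


@pytest.fixture(scope="session")
def h2():
    geometry = [("H", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, 0.74))]
    ao = ao_integrals(geometry, "sto-3g")
    mol = build_integrals(geometry, "sto-3g", ao=ao)
    spec = ActiveSpaceSpec.from_counts(mol, 2, 2)
    ham = fold_active_space(mol, spec)
    return {"geometry": geometry, "ao": ao, "mol": mol, "spec": spec,
            "ham": ham}
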