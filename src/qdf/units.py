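"""Physical constants and unit conversions (CODATA-consistent values).

Internal convention: electronic structure in Hartree atomic units,
geometries exchanged in Angstrom at the interfaces, molecular dynamics
bookkeeping in fs / amu / kcal/mol at the interfaces.
"""

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

HARTREE_TO_KCALMOL = 627.5095
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL

# Boltzmann constant in Hartree / K
KB_HARTREE = 3.166811563e-6

# 1 amu in electron masses
AMU_TO_AU = 1822.888486209

# 1 fs in atomic time units
FS_TO_AU = 41.341374575751

ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}

# Standard atomic masses (amu) for the elements the engine supports
ELEMENT_MASS = {
    "H": 1.00782503, "C": 12.0, "N": 14.0030740, "O": 15.9949146,
    "S": 31.9720707,
}
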