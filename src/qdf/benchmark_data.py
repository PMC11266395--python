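"""Published benchmark energies for the beta-lapachone prodrug activation
reaction (carbon-carbon bond cleavage).

Gibbs free energies (Hartree, thermal corrections included) for the five
species of the C-C cleavage step -- prodrug 4, transition state TS, and
products 5, 6 and water -- computed with HF and CASCI(2e,2o) on classical
hardware and measured in four independent VQE(2e,2o) experiments on a
superconducting quantum processor, with and without the continuum water
solvent.  These serve as reference inputs for assembling the reaction
profile 4 -> TS -> 5 + 6 + H2O.
"""

# species -> {"hf": G, "casci": G, "vqe": [4 repeats]}
WITH_SOLVENT = {
    "4":   {"hf": -1221.2446, "casci": -1221.2447,
            "vqe": [-1221.240, -1221.243, -1221.227, -1221.242]},
    "5":   {"hf": -343.3933, "casci": -343.4038,
            "vqe": [-343.395, -343.426, -343.403, -343.407]},
    "6":   {"hf": -801.8703, "casci": -801.8732,
            "vqe": [-801.866, -801.878, -801.859, -801.866]},
    "TS":  {"hf": -1221.2238, "casci": -1221.2259,
            "vqe": [-1221.224, -1221.232, -1221.223, -1221.230]},
    "H2O": {"hf": -76.0465, "casci": -76.0466,
            "vqe": [-76.043, -76.059, -76.036, -76.041]},
}

WITHOUT_SOLVENT = {
    "4":   {"hf": -1221.1821, "casci": -1221.1821,
            "vqe": [-1221.177, -1221.180, -1221.18, -1221.186]},
    "5":   {"hf": -343.3805, "casci": -343.3912,
            "vqe": [-343.390, -343.390, -343.391, -343.390]},
    "6":   {"hf": -801.8576, "casci": -801.8607,
            "vqe": [-801.856, -801.839, -801.857, -801.852]},
    "TS":  {"hf": -1221.178, "casci": -1221.180,
            "vqe": [-1221.181, -1221.187, -1221.179, -1221.207]},
    "H2O": {"hf": -76.0385, "casci": -76.0386,
            "vqe": [-76.029, -76.035, -76.059, -76.053]},
}

# C-C cleavage stoichiometry of the activation step
REACTANTS = ["4"]
TRANSITION_STATE = ["TS"]
PRODUCTS = ["5", "6", "H2O"]


def species_table(method: str, solvent: bool):
    """Build SpeciesEnergy objects for one method/solvent column."""
    from .thermo import SpeciesEnergy
    data = WITH_SOLVENT if solvent else WITHOUT_SOLVENT
    out = []
    for label, row in data.items():
        if method == "vqe":
            out.append(SpeciesEnergy(label=label, repeats=list(row["vqe"])))
        else:
            out.append(SpeciesEnergy(label=label,
                                     electronic_energy=row[method]))
    return out


def reaction_profile(method: str, solvent: bool):
    from .thermo import assemble_profile
    return assemble_profile(species_table(method, solvent),
                            REACTANTS, TRANSITION_STATE, PRODUCTS)
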