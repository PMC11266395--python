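"""Gibbs free-energy profiles for reaction energetics.

Assembles activation barriers (dG-dagger) and reaction free-energy changes
(dG) from per-species Gibbs energies, aggregates repeated sampled-VQE runs
into mean +- sample standard deviation, and propagates independent species
uncertainties by root-sum-square.  Energies are Hartree internally and
kcal/mol at the interface (conversion 627.5095).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import HARTREE_TO_KCALMOL


@dataclass
class SpeciesEnergy:
    label: str
    electronic_energy: float = None     # complete G in Hartree (see note)
    gibbs_correction: float = 0.0       # optional additive thermal correction
    repeats: list = None                # repeated sampled-VQE energies

    def gibbs(self):
        """(G, std): repeats aggregated when present, else deterministic."""
        if self.repeats:
            mean, std = aggregate_repeats(self.repeats)
            return mean + self.gibbs_correction, std
        if self.electronic_energy is None:
            raise ValueError(f"species {self.label!r} has no energy")
        return self.electronic_energy + self.gibbs_correction, 0.0


@dataclass
class ReactionProfile:
    reactants: list
    transition_state: list
    products: list
    dG_barrier: float           # kcal/mol
    dG_barrier_std: float
    dG_reaction: float          # kcal/mol
    dG_reaction_std: float


def aggregate_repeats(repeats):
    """Sample mean and standard deviation (ddof=1) of repeated runs."""
    repeats = np.asarray(list(repeats), dtype=float)
    if repeats.size == 0:
        raise ValueError("no repeats to aggregate")
    mean = float(repeats.mean())
    std = float(repeats.std(ddof=1)) if repeats.size > 1 else 0.0
    return mean, std


def parse_reaction(text):
    """Parse 'A + B -> TS -> C + D' into (reactants, ts, products)."""
    parts = [p.strip() for p in text.split("->")]
    if len(parts) != 3:
        raise ValueError("reaction must have the form 'R -> TS -> P'")
    split = lambda s: [x.strip() for x in s.split("+") if x.strip()]
    return split(parts[0]), split(parts[1]), split(parts[2])


def check_stoichiometry(species_formulas, reactants, ts, products):
    """Verify atom balance when formulas are provided (dict label->formula)."""
    def atoms(labels):
        count = {}
        for lab in labels:
            formula = species_formulas.get(lab)
            if formula is None:
                return None
            for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
                if el:
                    count[el] = count.get(el, 0) + (int(num) if num else 1)
        return count
    a_r, a_t, a_p = atoms(reactants), atoms(ts), atoms(products)
    if a_r is None or a_t is None or a_p is None:
        return True  # formulas not supplied; nothing to check
    if a_r != a_p or a_r != a_t:
        raise ValueError(f"unbalanced stoichiometry: {a_r} vs {a_t} vs {a_p}")
    return True


def assemble_profile(species, reactants, transition_state, products,
                     species_formulas=None) -> ReactionProfile:
    """Barrier and reaction free energy with uncertainty propagation.

    dG-dagger = G(TS) - sum G(reactants); dG = sum G(products) - sum
    G(reactants); stds combine as root-sum-square over the species involved
    (each species enters each difference once).
    """
    table = {s.label: s for s in species}
    for lab in list(reactants) + list(transition_state) + list(products):
        if lab not in table:
            raise ValueError(f"species {lab!r} missing from the table")
    if species_formulas:
        check_stoichiometry(species_formulas, reactants, transition_state,
                            products)

    def total(labels):
        g = 0.0
        var = 0.0
        for lab in labels:
            gi, si = table[lab].gibbs()
            g += gi
            var += si**2
        return g, var

    g_r, v_r = total(reactants)
    g_t, v_t = total(transition_state)
    g_p, v_p = total(products)
    h2k = HARTREE_TO_KCALMOL
    return ReactionProfile(
        reactants=list(reactants), transition_state=list(transition_state),
        products=list(products),
        dG_barrier=(g_t - g_r) * h2k,
        dG_barrier_std=float(np.sqrt(v_t + v_r)) * h2k,
        dG_reaction=(g_p - g_r) * h2k,
        dG_reaction_std=float(np.sqrt(v_p + v_r)) * h2k,
    )


def classify_spontaneity(profile: ReactionProfile, barrier_threshold=20.0):
    """Physiological-accessibility report for a reaction profile.

    A barrier strictly below ``barrier_threshold`` kcal/mol is flagged as
    accessible under biological conditions; negative barriers are flagged
    as non-physical (a sampled-noise artifact); negative dG is
    thermodynamically favorable.
    """
    report = {
        "barrier_kcal": profile.dG_barrier,
        "accessible": bool(profile.dG_barrier < barrier_threshold),
        "non_physical_barrier": bool(profile.dG_barrier < 0.0),
        "reaction_kcal": profile.dG_reaction,
        "favorable": bool(profile.dG_reaction < 0.0),
    }
    if report["non_physical_barrier"]:
        import warnings
        warnings.warn("negative activation barrier is non-physical; "
                      "likely measurement noise")
    return report


def species_from_csv(path):
    """Load a species table: columns label, energy, correction, repeat*."""
    df = pd.read_csv(path)
    out = []
    repeat_cols = [c for c in df.columns if c.startswith("repeat")]
    for _, row in df.iterrows():
        reps = [row[c] for c in repeat_cols if pd.notna(row.get(c))]
        out.append(SpeciesEnergy(
            label=str(row["label"]),
            electronic_energy=float(row["energy"]) if pd.notna(row.get("energy")) else None,
            gibbs_correction=float(row.get("correction", 0.0) or 0.0),
            repeats=reps or None))
    return out
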