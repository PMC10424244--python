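"""Element data and species/atom-name configuration tables.

Everything here is a plain module-level default that callers may override:
the residue-name -> species mapping, the head-reference atom of each lipid
species, the atom-name tables used for orientation axes, and per-element
soft-sphere radii for the clash relaxer.
"""

from __future__ import annotations

from .species import Species, Protonation

#: Atomic masses in Da (unified atomic mass units).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
}

#: Soft-sphere radii in Angstrom used by the clash relaxer (pair sigma = r_i + r_j).
#: Roughly half the van der Waals contact distance of each element.
SOFT_RADII: dict[str, float] = {
    "H": 0.6,
    "C": 1.0,
    "N": 0.95,
    "O": 0.9,
    "P": 1.1,
    "S": 1.1,
    "NA": 1.2,
    "CL": 1.2,
    "K": 1.4,
}
DEFAULT_SOFT_RADIUS = 1.0

#: Default residue-name -> (species, protonation) mapping used by the PDB reader.
SPECIES_MAP: dict[str, tuple[Species, Protonation]] = {
    "DSPC": (Species.DSPC, Protonation.NOT_APPLICABLE),
    "CHOL": (Species.CHOL, Protonation.NOT_APPLICABLE),
    "CHL1": (Species.CHOL, Protonation.NOT_APPLICABLE),
    "L5P": (Species.L5, Protonation.PROTONATED),
    "L5N": (Species.L5, Protonation.NEUTRAL),
    "TIP3": (Species.WATER, Protonation.NOT_APPLICABLE),
    "HOH": (Species.WATER, Protonation.NOT_APPLICABLE),
    "WAT": (Species.WATER, Protonation.NOT_APPLICABLE),
    "SOL": (Species.WATER, Protonation.NOT_APPLICABLE),
    "SOD": (Species.ION, Protonation.NOT_APPLICABLE),
    "CLA": (Species.ION, Protonation.NOT_APPLICABLE),
    "NA": (Species.ION, Protonation.NOT_APPLICABLE),
    "CL": (Species.ION, Protonation.NOT_APPLICABLE),
    "POT": (Species.ION, Protonation.NOT_APPLICABLE),
}

#: Residue names used when writing structures back out.
RESNAME_OF: dict[tuple[Species, Protonation], str] = {
    (Species.DSPC, Protonation.NOT_APPLICABLE): "DSPC",
    (Species.CHOL, Protonation.NOT_APPLICABLE): "CHOL",
    (Species.L5, Protonation.PROTONATED): "L5P",
    (Species.L5, Protonation.NEUTRAL): "L5N",
    (Species.WATER, Protonation.NOT_APPLICABLE): "TIP3",
    (Species.ION, Protonation.NOT_APPLICABLE): "SOD",
}

#: Head-reference atom per lipid species: phosphorus for the phospholipid,
#: the hydroxyl oxygen for cholesterol, the titratable nitrogen for the
#: ionizable aminolipid.
HEAD_ATOM: dict[Species, str] = {
    Species.DSPC: "P",
    Species.CHOL: "O3",
    Species.L5: "N",
}

#: Orientation-axis atom-name table: species -> (tail reference atom names,
#: head reference atom names).  The axis runs from the tail group's centre of
#: mass to the head group's centre of mass.
ORIENTATION_AXES: dict[Species, tuple[tuple[str, ...], tuple[str, ...]]] = {
    Species.L5: (("O1", "O2"), ("N",)),
    Species.DSPC: (("C2A", "C2B"), ("N", "P")),
}

#: First and last heavy atom of the designated unbranched tail, per species.
UNBRANCHED_TAIL: dict[Species, tuple[str, str]] = {
    Species.L5: ("C1B", "C4B"),
    Species.DSPC: ("C1B", "C2B"),
}


def element_of(atom_name: str) -> str:
    """Guess the element from a PDB-style atom name (first alphabetic char)."""
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            if stripped[:2].upper() in ("NA", "CL"):
                return stripped[:2].upper()
            return ch.upper()
    return "C"


def mass_of(element: str) -> float:
    return ATOMIC_MASS.get(element.upper(), 12.011)
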