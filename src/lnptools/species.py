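"""Species, protonation and leaflet labels."""

from __future__ import annotations

import enum


class Species(str, enum.Enum):
    """Molecular species of the model bilayer."""

    DSPC = "DSPC"   # structural phospholipid
    CHOL = "CHOL"   # cholesterol
    L5 = "L5"       # ionizable aminolipid (titratable amine head)
    WATER = "WATER"
    ION = "ION"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


LIPID_SPECIES = (Species.DSPC, Species.CHOL, Species.L5)


class Protonation(str, enum.Enum):
    PROTONATED = "protonated"
    NEUTRAL = "neutral"
    NOT_APPLICABLE = "not_applicable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Leaflet(str, enum.Enum):
    UPPER = "upper"
    LOWER = "lower"
    CORE = "core"
    UNASSIGNED = "unassigned"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value
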