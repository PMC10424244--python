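"""Inserted-species template: local-frame geometry of the ionizable aminolipid.

The template carries atom names/elements/coordinates in a local frame with
the head (titratable nitrogen) at the top, tails descending toward -z, plus
the bond list, the head atom, the two tail-anchor ester oxygens, and the
per-protonation-state variants.  Templates round-trip through JSON/YAML so a
user can supply their own lipid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import TopologyError
from .species import Protonation


@dataclass
class TemplateVariant:
    """Coordinates and formal charge of one protonation state."""

    coordinates: np.ndarray  # (n_atoms, 3), local frame
    charge: int


@dataclass
class LipidTemplate:
    name: str
    atom_names: list[str]
    elements: list[str]
    bonds: list[tuple[int, int]]  # indices into atom list
    head_atom: str
    tail_anchor_atoms: tuple[str, str]
    variants: dict[Protonation, TemplateVariant] = field(default_factory=dict)
    unbranched_tail: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.head_atom not in self.atom_names:
            raise TopologyError(f"head atom {self.head_atom!r} not in template atom list")
        for a in self.tail_anchor_atoms:
            if a not in self.atom_names:
                raise TopologyError(f"tail anchor {a!r} not in template atom list")
        for v in self.variants.values():
            v.coordinates = np.asarray(v.coordinates, dtype=float).reshape(
                len(self.atom_names), 3
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def index_of(self, atom_name: str) -> int:
        return self.atom_names.index(atom_name)

    def coordinates(self, variant: Protonation) -> np.ndarray:
        return self.variants[variant].coordinates

    def head_to_tail_axis(self, variant: Protonation) -> np.ndarray:
        """Unit vector from the head atom toward the tail-anchor midpoint."""
        coords = self.coordinates(variant)
        head = coords[self.index_of(self.head_atom)]
        mid = 0.5 * (
            coords[self.index_of(self.tail_anchor_atoms[0])]
            + coords[self.index_of(self.tail_anchor_atoms[1])]
        )
        v = mid - head
        return v / np.linalg.norm(v)

    def bounding_cylinder(self, variant: Protonation) -> tuple[float, float]:
        """(radius, length) of the axis-aligned bounding cylinder in the local frame."""
        coords = self.coordinates(variant)
        radius = float(np.sqrt((coords[:, :2] ** 2).sum(axis=1)).max())
        length = float(coords[:, 2].max() - coords[:, 2].min())
        return radius, length

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "atom_names": list(self.atom_names),
            "elements": list(self.elements),
            "bonds": [list(b) for b in self.bonds],
            "head_atom": self.head_atom,
            "tail_anchor_atoms": list(self.tail_anchor_atoms),
            "unbranched_tail": list(self.unbranched_tail) if self.unbranched_tail else None,
            "variants": {
                p.value: {"coordinates": v.coordinates.tolist(), "charge": v.charge}
                for p, v in self.variants.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LipidTemplate":
        return cls(
            name=d["name"],
            atom_names=list(d["atom_names"]),
            elements=list(d["elements"]),
            bonds=[tuple(b) for b in d["bonds"]],
            head_atom=d["head_atom"],
            tail_anchor_atoms=tuple(d["tail_anchor_atoms"]),
            unbranched_tail=tuple(d["unbranched_tail"]) if d.get("unbranched_tail") else None,
            variants={
                Protonation(k): TemplateVariant(
                    coordinates=np.asarray(v["coordinates"], dtype=float),
                    charge=int(v["charge"]),
                )
                for k, v in d["variants"].items()
            },
        )

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "LipidTemplate":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def default_l5_template() -> LipidTemplate:
    """Coarse template of the ionizable aminolipid.

    A titratable nitrogen head connected to two ester-bearing chains (chain B
    is the designated unbranched tail); head at the top of the local frame,
    tails descending toward -z.  Both protonation variants share coordinates
    and differ in formal charge.
    """
    names = ["N", "C1A", "O1", "C2A", "C3A", "C4A", "C1B", "O2", "C2B", "C3B", "C4B"]
    elements = ["N", "C", "O", "C", "C", "C", "C", "O", "C", "C", "C"]
    coords = np.array(
        [
            [0.0, 0.0, 0.0],     # N (head)
            [-1.3, 0.0, -2.0],   # chain A
            [-1.3, 0.0, -5.0],   # ester oxygen O1 (tail anchor)
            [-1.3, 0.0, -9.0],
            [-1.3, 0.0, -13.0],
            [-1.3, 0.0, -17.0],
            [1.3, 0.0, -2.0],    # chain B (unbranched)
            [1.3, 0.0, -5.0],    # ester oxygen O2 (tail anchor)
            [1.3, 0.0, -9.0],
            [1.3, 0.0, -13.0],
            [1.3, 0.0, -17.0],
        ]
    )
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 6), (6, 7), (7, 8), (8, 9), (9, 10)]
    return LipidTemplate(
        name="L5",
        atom_names=names,
        elements=elements,
        bonds=bonds,
        head_atom="N",
        tail_anchor_atoms=("O1", "O2"),
        unbranched_tail=("C1B", "C4B"),
        variants={
            Protonation.PROTONATED: TemplateVariant(coordinates=coords.copy(), charge=1),
            Protonation.NEUTRAL: TemplateVariant(coordinates=coords.copy(), charge=0),
        },
    )
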