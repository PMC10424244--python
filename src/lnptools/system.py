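"""In-memory model of a bilayer system: atoms, bonds, molecules, box.

The atom table is stored as numpy arrays for speed; :class:`AtomRecord` is a
lightweight per-atom view used for construction and inspection.  Molecules
carry the species / protonation / leaflet labels that every downstream
operation keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .errors import GeometryError, TopologyError
from .species import Leaflet, Protonation, Species, LIPID_SPECIES


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, naming and position (Angstrom)."""

    atom_id: int
    atom_name: str
    element: str
    residue_id: int
    residue_name: str
    position: tuple[float, float, float]


@dataclass
class Molecule:
    """A molecule with its species/protonation/leaflet labels and atom ids."""

    molecule_id: int
    species: Species
    protonation: Protonation = Protonation.NOT_APPLICABLE
    leaflet: Leaflet = Leaflet.UNASSIGNED
    atom_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atom_ids:
            raise TopologyError(f"molecule {self.molecule_id} has no atoms")
        if self.species is not Species.L5 and self.protonation is not Protonation.NOT_APPLICABLE:
            raise TopologyError(
                f"molecule {self.molecule_id}: protonation label only applies to L5"
            )


class MolecularSystem:
    """Atoms + bonds + molecules in an orthorhombic box.

    Invariants enforced on construction: unique atom ids, finite coordinates,
    every atom in exactly one molecule, bond endpoints present, positive box.
    """

    def __init__(
        self,
        atoms: list[AtomRecord],
        bonds: list[tuple[int, int]],
        molecules: list[Molecule],
        box,
    ) -> None:
        n = len(atoms)
        self.atom_ids = np.array([a.atom_id for a in atoms], dtype=np.int64)
        self.atom_names = np.array([a.atom_name for a in atoms], dtype=object)
        self.elements = np.array([a.element for a in atoms], dtype=object)
        self.residue_ids = np.array([a.residue_id for a in atoms], dtype=np.int64)
        self.residue_names = np.array([a.residue_name for a in atoms], dtype=object)
        self.positions = np.array([a.position for a in atoms], dtype=float).reshape(n, 3)
        self.bonds = np.array(bonds, dtype=np.int64).reshape(len(bonds), 2)
        self.molecules = list(molecules)
        self.box = np.asarray(box, dtype=float).reshape(3)
        self._index_of: dict[int, int] = {}
        self._mol_of_atom: dict[int, int] = {}
        self._reindex()
        self.validate()

    # ------------------------------------------------------------------
    def _reindex(self) -> None:
        self._index_of = {int(aid): i for i, aid in enumerate(self.atom_ids)}
        self._mol_of_atom = {}
        for mol in self.molecules:
            for aid in mol.atom_ids:
                self._mol_of_atom[int(aid)] = mol.molecule_id

    def validate(self) -> None:
        if len(self._index_of) != len(self.atom_ids):
            raise TopologyError("atom ids are not unique")
        if not np.all(np.isfinite(self.positions)):
            raise TopologyError("non-finite atom coordinates")
        if np.any(self.box <= 0):
            raise GeometryError(f"box components must be positive, got {self.box}")
        for a, b in self.bonds:
            if int(a) not in self._index_of or int(b) not in self._index_of:
                raise TopologyError(f"bond ({a}, {b}) references a missing atom id")
        seen: set[int] = set()
        for mol in self.molecules:
            for aid in mol.atom_ids:
                if aid in seen:
                    raise TopologyError(f"atom {aid} appears in more than one molecule")
                if aid not in self._index_of:
                    raise TopologyError(f"molecule {mol.molecule_id} references missing atom {aid}")
                seen.add(aid)
        if len(seen) != len(self.atom_ids):
            missing = set(int(i) for i in self.atom_ids) - seen
            raise TopologyError(f"atoms not assigned to any molecule: {sorted(missing)[:5]}...")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def index_of(self, atom_id: int) -> int:
        return self._index_of[int(atom_id)]

    def indices_of(self, atom_ids) -> np.ndarray:
        return np.array([self._index_of[int(a)] for a in atom_ids], dtype=np.intp)

    def atom(self, index: int) -> AtomRecord:
        return AtomRecord(
            atom_id=int(self.atom_ids[index]),
            atom_name=str(self.atom_names[index]),
            element=str(self.elements[index]),
            residue_id=int(self.residue_ids[index]),
            residue_name=str(self.residue_names[index]),
            position=tuple(self.positions[index]),
        )

    def iter_atoms(self):
        for i in range(self.n_atoms):
            yield self.atom(i)

    def molecule(self, molecule_id: int) -> Molecule:
        for mol in self.molecules:
            if mol.molecule_id == molecule_id:
                return mol
        raise KeyError(f"no molecule with id {molecule_id}")

    def molecule_of_atom(self, atom_id: int) -> int:
        return self._mol_of_atom[int(atom_id)]

    def molecules_of(self, species: Species, protonation: Protonation | None = None):
        out = [m for m in self.molecules if m.species is species]
        if protonation is not None:
            out = [m for m in out if m.protonation is protonation]
        return out

    def mol_positions(self, mol: Molecule) -> np.ndarray:
        return self.positions[self.indices_of(mol.atom_ids)]

    def named_atom_index(self, mol: Molecule, atom_name: str) -> int:
        for aid in mol.atom_ids:
            i = self._index_of[int(aid)]
            if str(self.atom_names[i]).strip() == atom_name:
                return i
        raise GeometryError(
            f"molecule {mol.molecule_id} ({mol.species}) has no atom named {atom_name!r}"
        )

    def head_atom_index(self, mol: Molecule, head_table: dict | None = None) -> int:
        table = head_table or chem.HEAD_ATOM
        try:
            name = table[mol.species]
        except KeyError:
            raise GeometryError(f"no head-reference atom configured for {mol.species}")
        return self.named_atom_index(mol, name)

    def masses(self) -> np.ndarray:
        return np.array([chem.mass_of(e) for e in self.elements], dtype=float)

    def copy(self) -> "MolecularSystem":
        new = object.__new__(MolecularSystem)
        new.atom_ids = self.atom_ids.copy()
        new.atom_names = self.atom_names.copy()
        new.elements = self.elements.copy()
        new.residue_ids = self.residue_ids.copy()
        new.residue_names = self.residue_names.copy()
        new.positions = self.positions.copy()
        new.bonds = self.bonds.copy()
        new.molecules = [
            Molecule(m.molecule_id, m.species, m.protonation, m.leaflet, list(m.atom_ids))
            for m in self.molecules
        ]
        new.box = self.box.copy()
        new._reindex()
        return new

    def remove_atoms(self, atom_ids) -> None:
        """Drop atoms (and their bonds) in place; molecule lists are untouched."""
        drop = {int(a) for a in atom_ids}
        keep = np.array([int(a) not in drop for a in self.atom_ids], dtype=bool)
        self.atom_ids = self.atom_ids[keep]
        self.atom_names = self.atom_names[keep]
        self.elements = self.elements[keep]
        self.residue_ids = self.residue_ids[keep]
        self.residue_names = self.residue_names[keep]
        self.positions = self.positions[keep]
        bond_keep = np.array(
            [int(a) not in drop and int(b) not in drop for a, b in self.bonds], dtype=bool
        )
        self.bonds = self.bonds[bond_keep]
        self._reindex()

    def append_atoms(self, atoms: list[AtomRecord], bonds: list[tuple[int, int]]) -> None:
        self.atom_ids = np.concatenate([self.atom_ids, [a.atom_id for a in atoms]])
        self.atom_names = np.concatenate([self.atom_names, [a.atom_name for a in atoms]])
        self.elements = np.concatenate([self.elements, [a.element for a in atoms]])
        self.residue_ids = np.concatenate([self.residue_ids, [a.residue_id for a in atoms]])
        self.residue_names = np.concatenate(
            [self.residue_names, [a.residue_name for a in atoms]]
        )
        self.positions = np.vstack([self.positions, [a.position for a in atoms]])
        if bonds:
            self.bonds = np.vstack([self.bonds, np.asarray(bonds, dtype=np.int64)])
        self._reindex()

    def next_atom_id(self) -> int:
        return int(self.atom_ids.max()) + 1 if len(self.atom_ids) else 1

    def next_molecule_id(self) -> int:
        return max((m.molecule_id for m in self.molecules), default=0) + 1

    def composition_counts(self) -> dict[str, int]:
        """Molecule counts keyed by species (L5 split by protonation)."""
        counts: dict[str, int] = {}
        for mol in self.molecules:
            if mol.species is Species.L5:
                key = f"L5_{mol.protonation.value}"
            else:
                key = mol.species.value
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass
class Trajectory:
    """Ordered frames of coordinates sharing one topology."""

    topology: MolecularSystem
    frames: list[np.ndarray]
    boxes: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                from .errors import ShapeError

                raise ShapeError(
                    f"frame {k} has shape {f.shape}, topology has {n} atoms"
                )
        if not self.boxes:
            self.boxes = [self.topology.box.copy() for _ in self.frames]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_system(self, k: int) -> MolecularSystem:
        sys_k = self.topology.copy()
        sys_k.positions = self.frames[k].copy()
        sys_k.box = np.asarray(self.boxes[k], dtype=float)
        return sys_k

    @classmethod
    def from_system(cls, system: MolecularSystem) -> "Trajectory":
        return cls(topology=system, frames=[system.positions.copy()], boxes=[system.box.copy()])


@dataclass(frozen=True)
class MembraneFrameGeometry:
    """Per-frame z landmarks: midplane, phosphate planes, water boundaries."""

    midplane_z: float
    upper_phosphate_z: float
    lower_phosphate_z: float
    water_boundary_upper_z: float | None = None
    water_boundary_lower_z: float | None = None

    def __post_init__(self) -> None:
        if not (self.lower_phosphate_z < self.midplane_z < self.upper_phosphate_z):
            raise GeometryError(
                "phosphate planes must straddle the midplane: "
                f"{self.lower_phosphate_z} < {self.midplane_z} < {self.upper_phosphate_z}"
            )


def _phosphorus_z(system: MolecularSystem, positions: np.ndarray) -> np.ndarray:
    zs = []
    for mol in system.molecules_of(Species.DSPC):
        for aid in mol.atom_ids:
            i = system.index_of(aid)
            if str(system.elements[i]).upper() == "P":
                zs.append(positions[i, 2])
    if not zs:
        raise GeometryError("no DSPC phosphorus atoms: cannot locate the midplane")
    return np.array(zs)


def midplane_z(system: MolecularSystem, positions: np.ndarray | None = None) -> float:
    """Mean z of all DSPC phosphorus atoms."""
    pos = system.positions if positions is None else positions
    return float(_phosphorus_z(system, pos).mean())


def membrane_geometry(
    system: MolecularSystem, positions: np.ndarray | None = None
) -> MembraneFrameGeometry:
    pos = system.positions if positions is None else positions
    pz = _phosphorus_z(system, pos)
    mid = float(pz.mean())
    upper = pz[pz > mid]
    lower = pz[pz <= mid]
    if len(upper) == 0 or len(lower) == 0:
        raise GeometryError("phosphorus atoms found in only one leaflet")
    water_hi: float | None = None
    water_lo: float | None = None
    wz = []
    for mol in system.molecules_of(Species.WATER):
        for aid in mol.atom_ids:
            i = system.index_of(aid)
            if str(system.elements[i]).upper() == "O":
                wz.append(pos[i, 2])
    if wz:
        wz = np.array(wz)
        above = wz[wz > mid]
        below = wz[wz <= mid]
        if len(above):
            water_hi = float(above.min())
        if len(below):
            water_lo = float(below.max())
    return MembraneFrameGeometry(
        midplane_z=mid,
        upper_phosphate_z=float(upper.mean()),
        lower_phosphate_z=float(lower.mean()),
        water_boundary_upper_z=water_hi,
        water_boundary_lower_z=water_lo,
    )


def assign_leaflets(
    system: MolecularSystem,
    core_band: float = 5.0,
    head_table: dict | None = None,
) -> MolecularSystem:
    """Label every lipid molecule upper / lower / core by its head-reference atom.

    The midplane is the mean z of all DSPC phosphorus atoms.  A lipid whose
    head-reference atom lies within ``core_band`` of the midplane is labeled
    ``core``; otherwise upper or lower by sign.  Water and ions stay
    unassigned.  Returns a labeled copy; invariant under global z-translation.
    """
    mid = midplane_z(system)
    out = system.copy()
    for mol in out.molecules:
        if mol.species not in LIPID_SPECIES:
            mol.leaflet = Leaflet.UNASSIGNED
            continue
        i = out.head_atom_index(mol, head_table)
        dz = out.positions[i, 2] - mid
        if abs(dz) <= core_band:
            mol.leaflet = Leaflet.CORE
        elif dz > 0:
            mol.leaflet = Leaflet.UPPER
        else:
            mol.leaflet = Leaflet.LOWER
    return out
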