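"""Structure and trajectory I/O.

PDB (ATOM/HETATM/CONECT/CRYST1/MODEL/ENDMDL) is the reference format; parsing
and writing are delegated to MDAnalysis.  A light pre-scan supplies the error
reporting the MDAnalysis reader is permissive about: malformed coordinate
fields are reported with their line number, and CONECT records that reference
absent serials raise a topology error instead of being dropped silently.

Inputs without CONECT records can carry molecule grouping in a sidecar
topology table (CSV: molecule_id, species, protonation, atom_ids).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np

from . import chem
from .errors import GeometryError, ParseError, ShapeError, TopologyError
from .species import Protonation, Species
from .system import AtomRecord, MolecularSystem, Molecule, Trajectory


def _prescan_pdb(path: Path) -> tuple[set[int], list[tuple[int, int]]]:
    """Validate ATOM/HETATM/CONECT records; return atom serials and CONECT pairs."""
    serials: set[int] = set()
    conect: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                try:
                    serial = int(line[6:11])
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed {rec} record: {exc}")
                serials.add(serial)
            elif rec == "CONECT":
                try:
                    fields = [int(line[i : i + 5]) for i in range(6, len(line.rstrip()), 5)
                              if line[i : i + 5].strip()]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed CONECT record: {exc}")
                base = fields[0]
                for other in fields[1:]:
                    conect.append((base, other))
    for a, b in conect:
        if a not in serials or b not in serials:
            raise TopologyError(
                f"{path}: CONECT ({a}, {b}) references a serial not present in the file"
            )
    return serials, conect


def read_topology_table(path) -> list[dict]:
    """Read a sidecar molecule table (molecule_id, species, protonation, atom_ids)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                {
                    "molecule_id": int(row["molecule_id"]),
                    "species": Species(row["species"].strip()),
                    "protonation": Protonation(row["protonation"].strip()),
                    "atom_ids": [int(t) for t in row["atom_ids"].split()],
                }
            )
    return rows


def _universe(path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(path))
        except (ValueError, IndexError, OSError) as exc:
            raise ParseError(f"could not parse {path}: {exc}")


def read_structure(
    path,
    format: str = "PDB",
    species_map: dict | None = None,
    topology_table=None,
    box=None,
) -> MolecularSystem:
    """Read a single-model PDB into a :class:`MolecularSystem`.

    Molecule grouping comes from the sidecar *topology_table* when given,
    otherwise one molecule per PDB residue; species are inferred from residue
    names through *species_map* (default :data:`lnptools.chem.SPECIES_MAP`).
    """
    if format.upper() != "PDB":
        raise ValueError(f"unsupported structure format: {format}")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    _prescan_pdb(path)
    u = _universe(path)
    smap = species_map or chem.SPECIES_MAP

    serials = u.atoms.ids.astype(int)
    names = [str(n) for n in u.atoms.names]
    try:
        elements = [str(e).upper() or chem.element_of(n) for e, n in zip(u.atoms.elements, names)]
    except Exception:
        elements = [chem.element_of(n) for n in names]
    resids = u.atoms.resids.astype(int)
    resnames = [str(r) for r in u.atoms.resnames]
    pos = u.atoms.positions.astype(float)

    atoms = [
        AtomRecord(int(serials[i]), names[i], elements[i], int(resids[i]), resnames[i],
                   tuple(pos[i]))
        for i in range(len(serials))
    ]

    bonds: list[tuple[int, int]] = []
    if hasattr(u, "bonds"):
        for b in u.bonds:
            i, j = b.indices
            bonds.append((int(serials[i]), int(serials[j])))

    if topology_table is not None:
        rows = (
            topology_table
            if isinstance(topology_table, list)
            else read_topology_table(topology_table)
        )
        molecules = [
            Molecule(r["molecule_id"], r["species"], r["protonation"], atom_ids=r["atom_ids"])
            for r in rows
        ]
    else:
        molecules = []
        for mol_idx, res in enumerate(u.residues, start=1):
            resname = str(res.resname).strip()
            if resname not in smap:
                raise TopologyError(
                    f"{path}: residue name {resname!r} has no species mapping; "
                    "extend species_map or provide a sidecar topology table"
                )
            sp, prot = smap[resname]
            molecules.append(
                Molecule(mol_idx, sp, prot, atom_ids=[int(serials[i]) for i in res.atoms.indices])
            )

    if box is None:
        dims = u.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise GeometryError(f"{path}: no CRYST1 record and no box supplied")
        box = dims[:3]
    return MolecularSystem(atoms=atoms, bonds=bonds, molecules=molecules, box=box)


def _mda_universe_from_system(system: MolecularSystem):
    import MDAnalysis as mda

    n = system.n_atoms
    resids = system.residue_ids
    # contiguous residue index per atom, preserving atom order
    res_index = np.zeros(n, dtype=int)
    res_ids, res_names = [], []
    last = None
    for i in range(n):
        key = int(resids[i])
        if last is None or key != last:
            res_ids.append(key)
            res_names.append(str(system.residue_names[i]))
            last = key
        res_index[i] = len(res_ids) - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n,
            n_residues=len(res_ids),
            atom_resindex=res_index,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(x) for x in system.atom_names])
        u.add_TopologyAttr("elements", [str(x) for x in system.elements])
        u.add_TopologyAttr("resids", res_ids)
        u.add_TopologyAttr("resnames", res_names)
        u.add_TopologyAttr("ids", system.atom_ids.astype(int))
        if len(system.bonds):
            idx = np.array(
                [[system.index_of(a), system.index_of(b)] for a, b in system.bonds]
            )
            u.add_TopologyAttr("bonds", idx)
        u.atoms.positions = system.positions
        u.dimensions = [*system.box, 90.0, 90.0, 90.0]
    return u


def write_structure(system: MolecularSystem, path) -> None:
    """Write a system to PDB, including CRYST1 and CONECT records."""
    u = _mda_universe_from_system(system)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path), bonds="conect" if len(system.bonds) else None)


def read_trajectory(path, topology: MolecularSystem) -> Trajectory:
    """Read a multi-model PDB as frames over an existing topology."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        u = _universe(path)
        frames = []
        boxes = []
        for ts in u.trajectory:
            if len(u.atoms) != topology.n_atoms:
                raise ShapeError(
                    f"{path}: frame has {len(u.atoms)} atoms, topology has {topology.n_atoms}"
                )
            frames.append(ts.positions.astype(float).copy())
            dims = ts.dimensions
            if dims is not None and np.all(dims[:3] > 0):
                boxes.append(np.array(dims[:3], dtype=float))
            else:
                boxes.append(topology.box.copy())
    except (ValueError, IndexError) as exc:
        raise ShapeError(f"{path}: inconsistent models: {exc}")
    if len(frames) and frames[0].shape[0] != topology.n_atoms:
        raise ShapeError(
            f"{path}: frames have {frames[0].shape[0]} atoms, topology has {topology.n_atoms}"
        )
    return Trajectory(topology=topology, frames=frames, boxes=boxes)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB."""
    import MDAnalysis as mda

    u = _mda_universe_from_system(traj.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=traj.topology.n_atoms) as w:
            for frame, box in zip(traj.frames, traj.boxes):
                u.atoms.positions = frame
                u.dimensions = [*box, 90.0, 90.0, 90.0]
                w.write(u.atoms)
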