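"""The six-step ionizable-lipid insertion workflow.

Starting from an equilibrated two-leaflet phospholipid/cholesterol bilayer:
(1) take the input structure, (2) randomly select the phospholipids to be
replaced (per leaflet, per the target composition), (3) build a cylindrical
repulsive grid potential at each selected site, (4) relax the surroundings
under the grids to carve cavities, (5) rigid-body place the aminolipid
template into each cavity, and (6) remove the grids on a linear eight-stage
force-constant schedule with a short relaxation per stage, then repair any
ring piercings of the cholesterol molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .composition import (
    CompositionSpec,
    assign_protonation_per_leaflet,
    plan_composition,
    select_replacements,
)
from .errors import PlacementError
from .geometry import pairwise_min_distance
from .grids import build_grid_potential, site_axis_of
from .rings import detect_ring_piercings, resolve_ring_piercings
from .relax import relax_with_grids
from .species import Leaflet, Protonation, Species
from .system import AtomRecord, MolecularSystem, assign_leaflets
from .template import LipidTemplate
from . import chem


@dataclass(frozen=True)
class RemovalSchedule:
    """Linear eight-stage force-constant ramp: k0 down to zero."""

    multipliers: tuple[float, ...]
    k0: float

    @property
    def constants(self) -> tuple[float, ...]:
        return tuple(self.k0 * m for m in self.multipliers)


def schedule_grid_removal(k0: float, n_stages: int = 8) -> RemovalSchedule:
    """Multipliers [1, (n-2)/(n-1), ..., 1/(n-1), 0]: first stage at full
    force constant, last with the grid gone, equal decrements in between."""
    if k0 < 0:
        raise ValueError(f"force constant k0 must be non-negative, got {k0}")
    m = tuple(float(x) for x in np.linspace(1.0, 0.0, n_stages))
    return RemovalSchedule(multipliers=m, k0=float(k0))


def place_template(
    site_molecule,
    system: MolecularSystem,
    template: LipidTemplate,
    variant: Protonation,
    rms_tol: float = 0.5,
) -> MolecularSystem:
    """Replace a site molecule's atoms with a rigid-body aligned template.

    The template head atom lands on the removed lipid's head position and the
    template head-to-tail axis is rotated onto the site axis (Kabsch fit over
    the head + two tail anchors).  The molecule record keeps its id and
    leaflet; species becomes L5 with the requested protonation.
    """
    out = system.copy()
    mol = out.molecule(site_molecule.molecule_id if hasattr(site_molecule, "molecule_id")
                       else site_molecule)
    head_pos, axis = site_axis_of(out, mol)

    coords = template.coordinates(variant)
    t_head = coords[template.index_of(template.head_atom)]
    t_a1 = coords[template.index_of(template.tail_anchor_atoms[0])]
    t_a2 = coords[template.index_of(template.tail_anchor_atoms[1])]
    t_axis = template.head_to_tail_axis(variant)

    # deterministic in-plane frame perpendicular to the site axis
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    t_perp = np.cross(t_axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(t_perp) < 1e-6:
        t_perp = np.cross(t_axis, [0.0, 1.0, 0.0])
    t_perp /= np.linalg.norm(t_perp)

    def _target(point: np.ndarray) -> np.ndarray:
        rel = point - t_head
        a = float(rel @ t_axis)
        p = float(rel @ t_perp)
        q_vec = rel - a * t_axis - p * t_perp
        q = float(q_vec @ np.cross(t_axis, t_perp))
        return head_pos + a * axis + p * perp + q * np.cross(axis, perp)

    src = np.array([t_head, t_a1, t_a2])
    dst = np.array([_target(p) for p in src])
    rot, rssd = Rotation.align_vectors(dst - dst.mean(axis=0), src - src.mean(axis=0))
    rms = rssd / np.sqrt(len(src))
    if rms > rms_tol:
        raise PlacementError(f"template alignment RMS {rms:.3f} A exceeds {rms_tol} A")
    placed = rot.apply(coords - t_head) + head_pos

    resid = int(out.residue_ids[out.index_of(mol.atom_ids[0])])
    out.remove_atoms(mol.atom_ids)
    start = out.next_atom_id()
    resname = chem.RESNAME_OF[(Species.L5, variant)]
    atoms = [
        AtomRecord(start + i, template.atom_names[i], template.elements[i], resid, resname,
                   tuple(placed[i]))
        for i in range(template.n_atoms)
    ]
    bonds = [(start + i, start + j) for i, j in template.bonds]
    out.append_atoms(atoms, bonds)
    mol.species = Species.L5
    mol.protonation = variant
    mol.atom_ids = [a.atom_id for a in atoms]
    out._reindex()
    out.validate()
    return out


@dataclass
class InsertionReport:
    counts: dict = field(default_factory=dict)
    counts_per_leaflet: dict = field(default_factory=dict)
    schedule: tuple[float, ...] = ()
    selected: list[int] = field(default_factory=list)
    piercings_detected: int = 0
    piercings_repaired: int = 0
    min_distance: float = float("inf")

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "counts_per_leaflet": self.counts_per_leaflet,
            "schedule": list(self.schedule),
            "selected_molecules": list(map(int, self.selected)),
            "piercings_detected": self.piercings_detected,
            "piercings_repaired": self.piercings_repaired,
            "min_distance": self.min_distance,
        }


def run_insertion(
    initial: MolecularSystem,
    spec: CompositionSpec,
    template: LipidTemplate,
    k0: float = 1.0,
    grid_spacing: float = 0.8,
    grid_resolution: float = 6.0,
    relax_steps: int = 120,
    stage_relax_steps: int = 25,
    clash_cutoff: float = 1.2,
    core_band: float = 5.0,
    return_report: bool = False,
):
    """Convert a phospholipid/cholesterol bilayer to the requested composition.

    Orchestrates selection, grid construction, relaxation, replacement, the
    staged grid removal, and ring repair.  Cholesterol molecules are never
    touched; molecule count is conserved exactly.
    """
    system = assign_leaflets(initial, core_band=core_band)
    counts = plan_composition(spec)
    n_l5 = {lf: c.n_l5 for lf, c in counts.items()}
    selected = select_replacements(
        system, n_l5, seed=spec.seed, replaceable=spec.replaceable_species
    )
    labels = assign_protonation_per_leaflet(
        n_l5, fraction=spec.protonated_fraction_of_l5, seed=spec.seed + 1
    )
    variant_of: dict[int, Protonation] = {}
    cursor = {lf: 0 for lf in labels}
    for mid in selected:
        lf = system.molecule(mid).leaflet
        variant_of[mid] = labels[lf][cursor[lf]]
        cursor[lf] += 1

    report = InsertionReport(selected=list(selected))

    grids = [
        build_grid_potential(
            system.molecule(mid), system, template,
            spacing=grid_spacing, resolution=grid_resolution, force_constant=k0,
        )
        for mid in selected
    ]

    if grids:
        system = relax_with_grids(system, grids, exempt=selected, max_steps=relax_steps)

    for mid in selected:
        system = place_template(system.molecule(mid), system, template, variant_of[mid])

    schedule = schedule_grid_removal(k0)
    report.schedule = schedule.constants
    if grids:
        # inserted lipids skip the grid energy but still repel neighbours
        for k_stage in schedule.constants:
            for g in grids:
                g.force_constant = k_stage
            system = relax_with_grids(
                system, grids, grid_exempt=selected, max_steps=stage_relax_steps
            )

    # ring repair can nudge atoms into contact and clash relaxation can in
    # principle re-thread a ring, so alternate until both conditions hold
    for attempt in range(4):
        violations = detect_ring_piercings(system)
        if attempt == 0:
            report.piercings_detected = len(violations)
        if violations:
            system = resolve_ring_piercings(system, violations)
            report.piercings_repaired += len(violations)
        system = relax_with_grids(system, [], max_steps=relax_steps)
        if (
            not detect_ring_piercings(system)
            and pairwise_min_distance(system.positions, system.box) >= clash_cutoff
        ):
            break

    system = assign_leaflets(system, core_band=core_band)
    report.counts = system.composition_counts()
    report.counts_per_leaflet = _counts_per_leaflet(system)
    report.min_distance = float(pairwise_min_distance(system.positions, system.box))
    if return_report:
        return system, report
    return system


def _counts_per_leaflet(system: MolecularSystem) -> dict:
    out: dict[str, dict[str, int]] = {}
    for mol in system.molecules:
        if mol.species in (Species.WATER, Species.ION):
            continue
        lf = mol.leaflet.value
        key = (
            f"L5_{mol.protonation.value}" if mol.species is Species.L5 else mol.species.value
        )
        out.setdefault(lf, {})
        out[lf][key] = out[lf].get(key, 0) + 1
    return out
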