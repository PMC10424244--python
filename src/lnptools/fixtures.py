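"""Synthetic bilayer structures and trajectories with planted statistics.

The generator emulates a two-leaflet DSPC/cholesterol (plus optional
ionizable aminolipid) bilayer on a square lattice: coarse placeholder lipids
with correctly named reference atoms (the phosphorus, hydroxyl oxygen and
titratable nitrogen heads, tail-anchor ester oxygens, tail beads, and a
six-membered cholesterol ring so ring-piercing code paths exercise), tilt
drawn per species from a wrapped-normal model, optional planted midplane
aggregates and planted z-density peaks, and frame jitter for trajectories.
Everything is deterministic under the fixture seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .composition import CompositionSpec, assign_protonation_per_leaflet, plan_composition
from .errors import FixtureError
from .geometry import pairwise_min_distance
from .species import Leaflet, Protonation, Species
from .system import AtomRecord, MolecularSystem, Molecule, Trajectory
from .template import default_l5_template
from . import chem


@dataclass
class TiltModel:
    """Wrapped-normal tilt: mean angle (deg) and concentration kappa.

    The tilt standard deviation is 1/sqrt(kappa) radians; kappa -> inf gives
    every molecule exactly the mean tilt.
    """

    mean_deg: float = 0.0
    kappa: float = 50.0

    def draw(self, rng: np.random.Generator) -> float:
        if np.isinf(self.kappa):
            return self.mean_deg
        sigma = np.degrees(1.0 / np.sqrt(self.kappa))
        theta = rng.normal(self.mean_deg, sigma)
        return float(abs((theta + 180.0) % 360.0 - 180.0))  # wrap into [0, 180]


@dataclass
class PlantedPeak:
    z: float                 # midplane-relative centre, Angstrom
    sigma: float
    count: int
    species: Species = Species.L5
    protonation: Protonation = Protonation.PROTONATED


@dataclass
class FixtureSpec:
    lattice_nx: int = 10
    lattice_ny: int = 10
    lattice_a: float = 8.0           # ~DSPC area per lipid
    leaflet_offset_z: float = 20.0   # phosphate plane height above the midplane
    composition: CompositionSpec = field(
        default_factory=lambda: CompositionSpec(
            total_lipids_per_leaflet=100, l5_fraction=0.0, chol_fraction=0.40
        )
    )
    tilt: dict = field(default_factory=dict)      # Species -> TiltModel
    box_z: float = 90.0
    water_mode: str = "none"         # "none" | "slab"
    water_boundary_z: float = 28.0   # innermost water plane (midplane-relative)
    water_spacing: float = 4.0
    water_layers: int = 2
    n_frames: int = 1
    jitter_sigma: float = 0.0
    seed: int = 0


# ----------------------------------------------------------------------
# local-frame placeholder geometries (head up, tails toward -z)

def _dspc_local():
    names = ["N", "P", "O21", "O31", "C1A", "C2A", "C1B", "C2B"]
    elements = ["N", "P", "O", "O", "C", "C", "C", "C"]
    coords = np.array(
        [
            [0.0, 0.0, 2.5],
            [0.0, 0.0, 0.0],
            [-1.2, 0.0, -2.0],
            [1.2, 0.0, -2.0],
            [-1.2, 0.0, -8.0],
            [-1.2, 0.0, -15.0],
            [1.2, 0.0, -8.0],
            [1.2, 0.0, -15.0],
        ]
    )
    bonds = [(0, 1), (1, 2), (1, 3), (2, 4), (4, 5), (3, 6), (6, 7)]
    return names, elements, coords, bonds, "P"


def _chol_local():
    # hydroxyl head plus a standing six-ring and a short tail
    names = ["O3", "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8"]
    elements = ["O", "C", "C", "C", "C", "C", "C", "C", "C"]
    ring_center = np.array([0.0, 0.0, -3.3])
    ring = [
        ring_center + 1.6 * np.array([np.cos(a), 0.0, np.sin(a)])
        for a in np.pi / 2 + np.linspace(0, 2 * np.pi, 6, endpoint=False)
    ]
    coords = np.array([[0.0, 0.0, 0.0], *ring, [0.0, 0.0, -7.0], [0.0, 0.0, -10.0]])
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1), (4, 7), (7, 8)]
    return names, elements, coords, bonds, "O3"


def _l5_local():
    t = default_l5_template()
    coords = t.coordinates(Protonation.PROTONATED)
    return t.atom_names, t.elements, coords, t.bonds, t.head_atom


_BUILDERS = {
    Species.DSPC: _dspc_local,
    Species.CHOL: _chol_local,
    Species.L5: _l5_local,
}

#: z of the head-reference atom relative to the phosphate plane, per species
_HEAD_OFFSET = {Species.DSPC: 0.0, Species.CHOL: -2.0, Species.L5: -1.0}


def _tilt_rotation(theta_deg: float, phi: float) -> Rotation:
    axis = np.array([np.cos(phi), np.sin(phi), 0.0])
    return Rotation.from_rotvec(np.radians(theta_deg) * axis)


def generate_bilayer(spec: FixtureSpec) -> MolecularSystem:
    """Two leaflets of placeholder lipids on a square lattice.

    Species are assigned per leaflet according to the composition spec (with
    the protonation split for any aminolipids), each molecule is tilted per
    its species tilt model, and the bilayer is centered at z = box_z / 2.
    """
    n_per_leaflet = spec.composition.total_lipids_per_leaflet
    n_sites = spec.lattice_nx * spec.lattice_ny
    if n_per_leaflet > n_sites:
        raise FixtureError(
            f"{n_per_leaflet} lipids per leaflet do not fit on a "
            f"{spec.lattice_nx}x{spec.lattice_ny} lattice"
        )
    counts = plan_composition(spec.composition)
    n_l5 = {lf: c.n_l5 for lf, c in counts.items()}
    prot_labels = assign_protonation_per_leaflet(
        n_l5, spec.composition.protonated_fraction_of_l5, seed=spec.seed + 7
    )
    rng = np.random.default_rng(spec.seed)
    box = np.array(
        [spec.lattice_nx * spec.lattice_a, spec.lattice_ny * spec.lattice_a, spec.box_z]
    )
    z_mid = spec.box_z / 2.0

    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    molecules: list[Molecule] = []
    next_atom = 1
    next_mol = 1

    for leaflet, sign in ((Leaflet.UPPER, +1.0), (Leaflet.LOWER, -1.0)):
        c = counts[leaflet]
        species_list = (
            [Species.DSPC] * c.n_dspc + [Species.CHOL] * c.n_chol + [Species.L5] * c.n_l5
        )
        rng.shuffle(species_list)
        sites = rng.permutation(n_sites)[:n_per_leaflet]
        l5_cursor = 0
        for site, sp in zip(sites, species_list):
            ix, iy = divmod(int(site), spec.lattice_ny)
            x = (ix + 0.5) * spec.lattice_a
            y = (iy + 0.5) * spec.lattice_a
            names, elements, local, lbonds, head_name = _BUILDERS[sp]()
            coords = local.copy()
            if sign < 0:
                coords[:, 2] *= -1.0
            tilt = spec.tilt.get(sp, TiltModel())
            theta = tilt.draw(rng)
            phi = rng.uniform(0, 2 * np.pi)
            head_i = names.index(head_name)
            head_local = coords[head_i]
            coords = _tilt_rotation(theta, phi).apply(coords - head_local) + head_local
            z_head = z_mid + sign * (spec.leaflet_offset_z + _HEAD_OFFSET[sp])
            coords += np.array([x, y, z_head]) - head_local
            prot = Protonation.NOT_APPLICABLE
            if sp is Species.L5:
                prot = prot_labels[leaflet][l5_cursor]
                l5_cursor += 1
            resname = chem.RESNAME_OF[(sp, prot)]
            ids = list(range(next_atom, next_atom + len(names)))
            atoms.extend(
                AtomRecord(ids[i], names[i], elements[i], next_mol, resname, tuple(coords[i]))
                for i in range(len(names))
            )
            bonds.extend((ids[i], ids[j]) for i, j in lbonds)
            molecules.append(
                Molecule(next_mol, sp, prot, leaflet, atom_ids=ids)
            )
            next_atom += len(names)
            next_mol += 1

    if spec.water_mode == "slab":
        nwx = max(int(box[0] // spec.water_spacing), 1)
        nwy = max(int(box[1] // spec.water_spacing), 1)
        for sign in (+1.0, -1.0):
            for layer in range(spec.water_layers):
                z = z_mid + sign * (spec.water_boundary_z + layer * spec.water_spacing)
                for ix in range(nwx):
                    for iy in range(nwy):
                        pos = (
                            (ix + 0.5) * spec.water_spacing,
                            (iy + 0.5) * spec.water_spacing,
                            z,
                        )
                        atoms.append(
                            AtomRecord(next_atom, "OH2", "O", next_mol, "TIP3", pos)
                        )
                        molecules.append(
                            Molecule(next_mol, Species.WATER, atom_ids=[next_atom])
                        )
                        next_atom += 1
                        next_mol += 1

    system = MolecularSystem(atoms=atoms, bonds=bonds, molecules=molecules, box=box)
    # tilted neighbours may touch: de-clash with rigid translations, which
    # leave the planted per-molecule tilt angles untouched
    if pairwise_min_distance(system.positions, system.box) < 1.5:
        from .relax import relax_with_grids

        system = relax_with_grids(system, grids=[], max_steps=150)
    if pairwise_min_distance(system.positions, system.box) < 1.5:
        raise FixtureError("generated lattice packs lipid atoms closer than 1.5 A")
    return system


def plant_core_aggregate(
    system: MolecularSystem, n: int, radius: float, seed: int = 0
) -> MolecularSystem:
    """Move *n* neutral aminolipids into a midplane blob of the given radius.

    Head nitrogens are placed uniformly inside a sphere centered on the box
    centre at the midplane; orientations are isotropic, emulating an
    amorphous droplet of the neutral species in the hydrophobic core.
    """
    out = system.copy()
    if n == 0:
        return out
    pool = out.molecules_of(Species.L5, Protonation.NEUTRAL)
    if n > len(pool):
        raise FixtureError(f"need {n} neutral L5 molecules, have {len(pool)}")
    rng = np.random.default_rng(seed)
    from .system import midplane_z as _mid

    try:
        z_mid = _mid(out)
    except Exception:
        z_mid = out.box[2] / 2.0
    center = np.array([out.box[0] / 2.0, out.box[1] / 2.0, z_mid])
    for mol in pool[:n]:
        idx = out.indices_of(mol.atom_ids)
        head_i = out.head_atom_index(mol)
        local = out.positions[idx] - out.positions[head_i]
        rot = Rotation.random(rng=rng)
        while True:
            p = rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p) <= radius:
                break
        out.positions[idx] = rot.apply(local) + center + p
        mol.leaflet = Leaflet.CORE
    return out


def generate_trajectory(
    system: MolecularSystem, n_frames: int, jitter_sigma: float = 0.0, seed: int = 0
) -> Trajectory:
    """Frames of independent Gaussian positional jitter around the base system."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        noise = (
            rng.normal(0.0, jitter_sigma, size=system.positions.shape)
            if jitter_sigma > 0
            else 0.0
        )
        frames.append(system.positions + noise)
    return Trajectory(
        topology=system, frames=frames, boxes=[system.box.copy() for _ in range(n_frames)]
    )


def plant_density_population(
    system: MolecularSystem, peaks: list[PlantedPeak], seed: int = 0
) -> MolecularSystem:
    """Add single-atom marker molecules with z drawn from planted Gaussians.

    Each marker carries the head-reference atom name of its species (the
    titratable nitrogen for the aminolipid), so density selections pick it
    up; x-y positions are uniform over the box.
    """
    out = system.copy()
    rng = np.random.default_rng(seed)
    from .system import midplane_z as _mid

    try:
        z_mid = _mid(out)
    except Exception:
        z_mid = out.box[2] / 2.0
    next_atom = out.next_atom_id()
    next_mol = out.next_molecule_id()
    new_atoms: list[AtomRecord] = []
    for peak in peaks:
        if peak.count < 0:
            raise FixtureError("planted peak count must be non-negative")
        if peak.count == 0:
            continue
        name = chem.HEAD_ATOM[peak.species]
        element = chem.element_of(name)
        resname = chem.RESNAME_OF[(peak.species, peak.protonation)]
        xs = rng.uniform(0, out.box[0], peak.count)
        ys = rng.uniform(0, out.box[1], peak.count)
        zs = z_mid + rng.normal(peak.z, peak.sigma, peak.count)
        for j in range(peak.count):
            new_atoms.append(
                AtomRecord(next_atom, name, element, next_mol, resname,
                           (float(xs[j]), float(ys[j]), float(zs[j])))
            )
            out.molecules.append(
                Molecule(next_mol, peak.species, peak.protonation, atom_ids=[next_atom])
            )
            next_atom += 1
            next_mol += 1
    if new_atoms:
        out.append_atoms(new_atoms, [])
        out.validate()
    return out
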