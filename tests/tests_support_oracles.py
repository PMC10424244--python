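"""Independent oracles shared by the test suite.

These deliberately re-derive results by different algorithms than the
package: Moller-Trumbore segment/triangle intersection over a fan
triangulation for ring piercing, breadth-first density reachability for
DBSCAN, and a Poisson-process reference for the lateral RDF.
"""

import numpy as np

from lnptools.geometry import minimum_image_distance_matrix
from lnptools.species import Leaflet, Protonation, Species
from lnptools.system import AtomRecord, MolecularSystem, Molecule, Trajectory

RING_BOX = (60.0, 60.0, 60.0)


def hexagon(center, normal, radius=1.6, rng=None):
    """Vertices of a planar hexagon with the given unit normal."""
    normal = np.asarray(normal, dtype=float)
    normal /= np.linalg.norm(normal)
    e1 = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(normal, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    if rng is not None:
        angles += rng.uniform(0, 2 * np.pi)
    return np.array([center + radius * (np.cos(a) * e1 + np.sin(a) * e2) for a in angles])


def build_ring_system(ring_vertices, segment, box=RING_BOX):
    """System with one 6-ring molecule and one 2-atom bonded segment."""
    atoms = [
        AtomRecord(i + 1, f"C{i + 1}", "C", 1, "CHOL", tuple(ring_vertices[i]))
        for i in range(6)
    ]
    ring_bonds = [(i + 1, (i + 1) % 6 + 1) for i in range(6)]
    atoms += [
        AtomRecord(7, "C1A", "C", 2, "DSPC", tuple(segment[0])),
        AtomRecord(8, "C2A", "C", 2, "DSPC", tuple(segment[1])),
    ]
    mols = [
        Molecule(1, Species.CHOL, atom_ids=[1, 2, 3, 4, 5, 6]),
        Molecule(2, Species.DSPC, atom_ids=[7, 8]),
    ]
    return MolecularSystem(atoms=atoms, bonds=ring_bonds + [(7, 8)], molecules=mols, box=box)


def random_ring_instance(rng):
    """Randomized hexagon + nearby segment; returns (system, segment, ring)."""
    center = rng.uniform(20, 40, 3)
    normal = rng.normal(size=3)
    ring = hexagon(center, normal, rng=rng)
    mid = center + rng.uniform(-2.0, 2.0, 3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    half = rng.uniform(1.0, 3.0)
    seg = np.array([mid - half * direction, mid + half * direction])
    return build_ring_system(ring, seg), seg, ring


def _segment_triangle(p0, p1, a, b, c, eps=1e-12):
    d = p1 - p0
    e1, e2 = b - a, c - a
    h = np.cross(d, e2)
    det = e1 @ h
    if abs(det) < eps:
        return False
    inv = 1.0 / det
    s = p0 - a
    u = inv * (s @ h)
    if u < 0 or u > 1:
        return False
    q = np.cross(s, e1)
    v = inv * (d @ q)
    if v < 0 or u + v > 1:
        return False
    t = inv * (e2 @ q)
    return 0.0 < t < 1.0


def oracle_pierces(segment, ring_vertices):
    """Fan-triangulated segment/polygon intersection."""
    centroid = ring_vertices.mean(axis=0)
    n = len(ring_vertices)
    for i in range(n):
        if _segment_triangle(
            segment[0], segment[1], centroid, ring_vertices[i], ring_vertices[(i + 1) % n]
        ):
            return True
    return False


def brute_force_dbscan(points, box, eps, min_points):
    """Density-reachability clustering by breadth-first search from core points."""
    d = minimum_image_distance_matrix(points, np.asarray(box, dtype=float))
    n = len(points)
    neighbors = [np.nonzero(d[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= min_points for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        queue.append(k)
        cluster += 1
    return labels


def same_partition(a, b):
    """Identical clusterings up to label permutation (noise sets must match)."""
    a, b = np.asarray(a), np.asarray(b)
    if len(a) != len(b) or not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


def point_molecule_system(xy_points, box=(125.0, 125.0, 90.0), zs=None):
    """One-atom protonated aminolipid molecules at given in-plane positions."""
    atoms = [
        AtomRecord(1, "P", "P", 1, "DSPC", (1.0, 1.0, 65.0)),
        AtomRecord(2, "P", "P", 2, "DSPC", (2.0, 2.0, 25.0)),
    ]
    mols = [
        Molecule(1, Species.DSPC, atom_ids=[1]),
        Molecule(2, Species.DSPC, atom_ids=[2]),
    ]
    aid = 3
    for k, (x, y) in enumerate(xy_points):
        z = 45.0 if zs is None else zs[k]
        atoms.append(AtomRecord(aid, "N", "N", aid, "L5P", (float(x), float(y), float(z))))
        mols.append(
            Molecule(aid, Species.L5, Protonation.PROTONATED, Leaflet.UPPER, atom_ids=[aid])
        )
        aid += 1
    return MolecularSystem(atoms=atoms, bonds=[], molecules=mols, box=box)


def poisson_rdf(n_points=1000, n_frames=25, seed=0, box_l=125.0):
    """Lateral RDF of frames of independent uniform in-plane scatter."""
    from lnptools import analysis as an

    rng = np.random.default_rng(seed)
    base = None
    frames = []
    for _ in range(n_frames):
        pts = np.column_stack(
            [rng.uniform(0, box_l, n_points), rng.uniform(0, box_l, n_points)]
        )
        sys_f = point_molecule_system(pts, box=(box_l, box_l, 90.0))
        if base is None:
            base = sys_f
        frames.append(sys_f.positions.copy())
    traj = Trajectory(topology=base, frames=frames)
    rdf = an.lateral_rdf(traj, an.molecule_selector(species=Species.L5))
    return rdf, box_l
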