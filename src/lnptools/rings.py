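"""Ring-piercing detection and repair.

A ring piercing is a starting-structure artifact in which a bond threads
through a ring (cholesterol's fused rings are the usual victim).  Rings are
the 5- and 6-cycles of the bond graph; a bond between two atoms outside a
ring pierces it when the bond segment crosses the ring's best-fit plane and
the crossing point falls inside the ring polygon projected onto that plane.
Repair translates the offending bond's atoms along the ring normal, toward
the nearer exit, until the piercing clears.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from shapely.geometry import Point, Polygon

from .errors import RepairError
from .geometry import wrap_displacements
from .system import MolecularSystem

RING_SIZES = (5, 6)


@dataclass(frozen=True)
class PiercingViolation:
    bond: tuple[int, int]            # atom ids
    ring: tuple[int, ...]            # ordered atom-id cycle
    intersection_point: tuple[float, float, float]


def ring_cycles(system: MolecularSystem) -> list[list[int]]:
    """Ordered 5-/6-cycles of the bond graph (atom ids)."""
    if len(system.bonds) == 0:
        return []
    g = nx.Graph()
    g.add_edges_from((int(a), int(b)) for a, b in system.bonds)
    cycles = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for cyc in nx.cycle_basis(sub):
            if len(cyc) in RING_SIZES:
                cycles.append([int(a) for a in cyc])
    return cycles


def _ring_frame(ring_pos: np.ndarray):
    """Best-fit plane of a ring: (centroid, unit normal, in-plane basis e1/e2)."""
    centroid = ring_pos.mean(axis=0)
    rel = ring_pos - centroid
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    normal = vt[2]
    # deterministic sign: largest-magnitude component positive
    lead = int(np.argmax(np.abs(normal)))
    if normal[lead] < 0:
        normal = -normal
    e1, e2 = vt[0], vt[1]
    return centroid, normal, e1, e2


def _segment_hits_ring(p1, p2, ring_pos) -> np.ndarray | None:
    """Intersection point if segment p1-p2 pierces the ring polygon, else None."""
    centroid, normal, e1, e2 = _ring_frame(ring_pos)
    s1 = float((p1 - centroid) @ normal)
    s2 = float((p2 - centroid) @ normal)
    if s1 * s2 >= 0:
        return None
    t = s1 / (s1 - s2)
    hit = p1 + t * (p2 - p1)
    poly = Polygon((ring_pos - centroid) @ np.column_stack([e1, e2]))
    uv = Point(float((hit - centroid) @ e1), float((hit - centroid) @ e2))
    return hit if poly.contains(uv) else None


def detect_ring_piercings(system: MolecularSystem) -> list[PiercingViolation]:
    """All bonds that thread through a 5-/6-ring of another part of the system."""
    cycles = ring_cycles(system)
    if not cycles or len(system.bonds) == 0:
        return []
    box = system.box
    violations: list[PiercingViolation] = []
    bond_idx = np.array(
        [[system.index_of(a), system.index_of(b)] for a, b in system.bonds], dtype=int
    )
    b1 = system.positions[bond_idx[:, 0]]
    # bonds may straddle the box face: use the minimum-image bond vector
    b2 = b1 + wrap_displacements(system.positions[bond_idx[:, 1]] - b1, box)
    mid = 0.5 * (b1 + b2)
    for ring in cycles:
        ring_set = set(ring)
        ridx = system.indices_of(ring)
        ring_pos = system.positions[ridx]
        centroid = ring_pos.mean(axis=0)
        reach = float(np.linalg.norm(ring_pos - centroid, axis=1).max()) + 2.0
        # minimum-image shift of every bond toward the ring's image
        shift = wrap_displacements(mid - centroid, box) - (mid - centroid)
        near = np.linalg.norm(mid + shift - centroid, axis=1) < reach + 1.5
        for k in np.nonzero(near)[0]:
            a_id, b_id = int(system.bonds[k, 0]), int(system.bonds[k, 1])
            if a_id in ring_set or b_id in ring_set:
                continue
            hit = _segment_hits_ring(b1[k] + shift[k], b2[k] + shift[k], ring_pos)
            if hit is not None:
                violations.append(
                    PiercingViolation(
                        bond=(a_id, b_id),
                        ring=tuple(ring),
                        intersection_point=tuple(hit - shift[k]),
                    )
                )
    return violations


def resolve_ring_piercings(
    system: MolecularSystem,
    violations: list[PiercingViolation],
    step: float = 0.3,
    max_pushes: int = 40,
    max_rounds: int = 10,
) -> MolecularSystem:
    """Translate offending bond atoms along the ring normal until clear.

    Only the two atoms of each piercing bond move; the sign of the normal is
    chosen toward the nearer exit (the side of the plane whose bond endpoint
    is closer to it).  Detection is re-run until no piercing remains.
    """
    out = system.copy()
    if not violations:
        return out
    pending = list(violations)
    # once a chain picks an exit side of a ring, its other bonds follow it,
    # otherwise clearing one bond can push its neighbour back through
    chosen_sign: dict[tuple, float] = {}
    for _ in range(max_rounds):
        for v in pending:
            ia, ib = out.index_of(v.bond[0]), out.index_of(v.bond[1])
            key = (v.ring, out.molecule_of_atom(v.bond[0]))
            ridx = out.indices_of(v.ring)
            for _ in range(max_pushes):
                ring_pos = out.positions[ridx]
                centroid, normal, _, _ = _ring_frame(ring_pos)
                p1 = out.positions[ia]
                p2 = p1 + wrap_displacements(out.positions[ib] - p1, out.box)
                mid = 0.5 * (p1 + p2)
                shift = wrap_displacements(mid - centroid, out.box) - (mid - centroid)
                if _segment_hits_ring(p1 + shift, p2 + shift, ring_pos) is None:
                    break
                s1 = float((p1 + shift - centroid) @ normal)
                s2 = float((p2 + shift - centroid) @ normal)
                if key in chosen_sign:
                    sign = chosen_sign[key]
                else:
                    sign = float(np.sign(s1 if abs(s1) < abs(s2) else s2) or 1.0)
                    chosen_sign[key] = sign
                out.positions[ia] += sign * step * normal
                out.positions[ib] += sign * step * normal
        pending = detect_ring_piercings(out)
        if not pending:
            return out
    raise RepairError(f"{len(pending)} ring piercings left after {max_rounds} repair rounds")
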