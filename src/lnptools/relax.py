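"""Deterministic cavity relaxation.

Replaces the molecular-dynamics stages of the insertion protocol with
steepest descent on a desk-scale energy: the repulsive grid energy of all
non-exempt atoms plus a purely repulsive soft-sphere pair potential between
atoms of different molecules.  Molecules move as rigid bodies (translation
only), so intramolecular geometry is preserved and bonded terms are not
needed.  The descent uses backtracking, so total energy is non-increasing at
every accepted step.

Inside a grid cylinder the field is flat (value 1) and the gradient
vanishes; atoms trapped there are walked out along the cylinder's outward
radial direction, which leaves the energy unchanged until they reach the
smoothed shoulder and start descending.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .errors import NumericalError
from .grids import GridPotential
from .system import MolecularSystem


def _soft_radii(elements, radii: dict | None) -> np.ndarray:
    table = radii or chem.SOFT_RADII
    return np.array(
        [table.get(str(e).upper(), chem.DEFAULT_SOFT_RADIUS) for e in elements], dtype=float
    )


class _RelaxState:
    """Movable-atom bookkeeping for one relaxation run."""

    def __init__(
        self,
        system: MolecularSystem,
        exempt: set[int],
        radii,
        cutoff: float,
        grid_exempt: set[int] = frozenset(),
    ):
        self.box = system.box.copy()
        self.cutoff = cutoff
        movable_mols = [m for m in system.molecules if m.molecule_id not in exempt]
        self.grid_mask = np.concatenate(
            [
                np.full(len(m.atom_ids), m.molecule_id not in grid_exempt)
                for m in movable_mols
            ]
        ) if movable_mols else np.array([], bool)
        self.mol_atom_idx = [system.indices_of(m.atom_ids) for m in movable_mols]
        self.atom_idx = np.concatenate(self.mol_atom_idx) if movable_mols else np.array([], int)
        self.mol_slot = np.concatenate(
            [np.full(len(idx), s, dtype=int) for s, idx in enumerate(self.mol_atom_idx)]
        ) if movable_mols else np.array([], int)
        self.n_mols = len(movable_mols)
        self.sigma_atom = _soft_radii(system.elements[self.atom_idx], radii)
        self.pairs: np.ndarray | None = None
        self.sig_pair: np.ndarray | None = None

    def build_pairs(self, pos_movable: np.ndarray, skin: float = 1.0) -> None:
        if len(pos_movable) < 2:
            self.pairs = np.empty((0, 2), dtype=int)
            self.sig_pair = np.empty(0)
            return
        wrapped = np.mod(pos_movable, self.box)
        wrapped = np.where(wrapped >= self.box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=self.box)
        pairs = tree.query_pairs(self.cutoff + skin, output_type="ndarray")
        if len(pairs):
            keep = self.mol_slot[pairs[:, 0]] != self.mol_slot[pairs[:, 1]]
            pairs = pairs[keep]
        self.pairs = pairs
        self.sig_pair = self.sigma_atom[pairs[:, 0]] + self.sigma_atom[pairs[:, 1]]


def _pair_energy_forces(
    state: _RelaxState, pos: np.ndarray, eps: float, want_forces: bool
) -> tuple[float, np.ndarray | None]:
    pairs = state.pairs
    forces = np.zeros_like(pos) if want_forces else None
    if pairs is None or len(pairs) == 0:
        return 0.0, forces
    d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    d -= state.box * np.round(d / state.box)
    r2 = (d ** 2).sum(axis=1)
    rc = state.cutoff
    mask = r2 < rc ** 2
    if not mask.any():
        return 0.0, forces
    d = d[mask]
    r2 = np.maximum(r2[mask], 1e-4)
    sig = state.sig_pair[mask]
    inv = sig ** 2 / r2
    u = inv ** 6
    shift = (sig / rc) ** 12
    energy = float(eps * np.sum(u - shift))
    if want_forces:
        fmag = 12.0 * eps * u / r2  # dU/dr / r, pointing i away from j
        fv = fmag[:, None] * d
        np.add.at(forces, pairs[mask, 0], fv)
        np.add.at(forces, pairs[mask, 1], -fv)
    return energy, forces


def _grid_candidates(
    grids: list[GridPotential],
    pos: np.ndarray,
    grid_mask: np.ndarray | None,
    margin: float,
) -> list[np.ndarray]:
    """Per-grid indices of atoms within the lattice extent (plus a motion margin)."""
    cands = []
    for g in grids:
        if g.force_constant == 0.0:
            cands.append(np.empty(0, dtype=np.intp))
            continue
        lo, hi = g.origin - margin, g.extent + margin
        in_box = np.all((pos >= lo) & (pos <= hi), axis=1)
        if grid_mask is not None:
            in_box &= grid_mask
        cands.append(np.nonzero(in_box)[0])
    return cands


def _grid_energy_forces(
    grids: list[GridPotential],
    pos: np.ndarray,
    want_forces: bool,
    candidates: list[np.ndarray],
    plateau_tol: float = 0.05,
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """Returns (energy, forces, plateau escape directions)."""
    energy = 0.0
    forces = np.zeros_like(pos) if want_forces else None
    plateau = np.zeros_like(pos) if want_forces else None
    for g, cand in zip(grids, candidates):
        if g.force_constant == 0.0 or len(cand) == 0:
            continue
        vals, grads = g.interpolate(pos[cand], want_gradient=want_forces)
        energy += g.force_constant * float(vals.sum())
        if want_forces:
            forces[cand] -= g.force_constant * grads
            # high-field atoms whose grid force is too weak to drive descent
            # (the plateau inside the cylinder, or its nearly-flat rim)
            flat = (vals >= 0.5) & (
                g.force_constant * np.linalg.norm(grads, axis=1) < plateau_tol
            )
            if flat.any():
                esc = g.outward_radial(pos[cand[flat]])
                plateau[cand[flat]] += g.force_constant * esc
    return energy, forces, plateau


def relax_with_grids(
    system: MolecularSystem,
    grids: list[GridPotential],
    exempt=(),
    max_steps: int = 200,
    force_tol: float = 0.05,
    step_size: float = 0.3,
    cutoff: float = 9.0,
    eps: float = 1.0,
    radii: dict | None = None,
    grid_exempt=(),
    return_info: bool = False,
):
    """Steepest-descent relaxation under grid potentials + soft-sphere repulsion.

    *exempt* molecules (the lipids awaiting replacement) feel no forces and
    exert none; *grid_exempt* molecules (freshly inserted lipids during the
    staged removal) skip the grid energy but still repel their neighbours.
    Terminates when the largest per-molecule force drops below *force_tol*
    (with no atoms left on a grid plateau) or after *max_steps*.
    """
    out = system.copy()
    state = _RelaxState(out, set(exempt), radii, cutoff, grid_exempt=set(grid_exempt))
    if state.n_mols == 0:
        return (out, {"energy": [], "steps": 0}) if return_info else out

    pos = out.positions[state.atom_idx].copy()
    energies: list[float] = []
    cands: list[np.ndarray] = []

    def total_energy(p: np.ndarray) -> float:
        e_pair, _ = _pair_energy_forces(state, p, eps, want_forces=False)
        e_grid, _, _ = _grid_energy_forces(grids, p, want_forces=False, candidates=cands)
        return e_pair + e_grid

    steps_done = 0
    refresh = 5  # candidate/neighbour refresh interval, covered by the margin
    for step in range(max_steps):
        if step % refresh == 0:
            # skin covers the maximum drift of two atoms between rebuilds
            state.build_pairs(pos, skin=2.0 * (refresh + 1) * step_size)
            cands = _grid_candidates(
                grids, pos, state.grid_mask, margin=(refresh + 1) * step_size
            )
        e_pair, f_pair = _pair_energy_forces(state, pos, eps, want_forces=True)
        e_grid, f_grid, plateau = _grid_energy_forces(
            grids, pos, want_forces=True, candidates=cands, plateau_tol=force_tol,
        )
        energy = e_pair + e_grid
        if not np.isfinite(energy):
            raise NumericalError("non-finite relaxation energy")
        energies.append(energy)
        f_atom = f_pair + f_grid
        f_mol = np.zeros((state.n_mols, 3))
        np.add.at(f_mol, state.mol_slot, f_atom)
        p_mol = np.zeros((state.n_mols, 3))
        np.add.at(p_mol, state.mol_slot, plateau)
        max_force = float(np.linalg.norm(f_mol, axis=1).max())
        has_plateau = bool(np.abs(plateau).max() > 0)
        if max_force < force_tol and not has_plateau:
            break
        direction = f_mol + p_mol
        dmax = float(np.linalg.norm(direction, axis=1).max())
        if dmax < 1e-12:
            break
        lam = step_size / dmax
        accepted = False
        for _ in range(10):
            trial = pos + lam * direction[state.mol_slot]
            if total_energy(trial) <= energy + 1e-10:
                pos = trial
                accepted = True
                break
            lam *= 0.5
        steps_done = step + 1
        if not accepted:
            break

    out.positions[state.atom_idx] = pos
    if return_info:
        final = total_energy(pos)
        energies.append(final)
        return out, {"energy": energies, "steps": steps_done}
    return out
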