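"""Composition planning and protonation assignment.

The bilayer recipe keeps cholesterol at a fixed mole fraction (default 40%)
while a chosen fraction of the phospholipid population is replaced by the
ionizable aminolipid; half of the aminolipids are protonated and half
neutral by default, mirroring the roughly even charge split expected at the
working pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CompositionError, SelectionError
from .species import Leaflet, Protonation, Species
from .system import MolecularSystem


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CompositionSpec:
    """Target per-leaflet composition of the converted bilayer."""

    total_lipids_per_leaflet: int
    l5_fraction: float
    chol_fraction: float = 0.40
    protonated_fraction_of_l5: float = 0.5
    replaceable_species: Species = Species.DSPC
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("l5_fraction", "chol_fraction", "protonated_fraction_of_l5"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CompositionError(f"{name}={v} outside [0, 1]")
        if self.l5_fraction + self.chol_fraction > 1.0 + 1e-12:
            raise CompositionError(
                f"l5_fraction + chol_fraction = {self.l5_fraction + self.chol_fraction} > 1"
            )
        if self.total_lipids_per_leaflet < 0:
            raise CompositionError("total_lipids_per_leaflet must be non-negative")


@dataclass
class LeafletCounts:
    n_dspc: int
    n_chol: int
    n_l5: int

    @property
    def total(self) -> int:
        return self.n_dspc + self.n_chol + self.n_l5


def plan_composition(spec: CompositionSpec) -> dict[Leaflet, LeafletCounts]:
    """Deterministic per-leaflet species counts for a composition spec.

    ``n_chol = round(chol_fraction * N)``, ``n_l5 = round(l5_fraction * N)``,
    remainder phospholipid; identical for both leaflets.
    """
    n = spec.total_lipids_per_leaflet
    n_chol = _round_half_up(spec.chol_fraction * n)
    n_l5 = _round_half_up(spec.l5_fraction * n)
    n_dspc = n - n_chol - n_l5
    if n_dspc < 0:
        raise CompositionError(
            f"infeasible composition: chol {n_chol} + L5 {n_l5} exceeds {n} lipids per leaflet"
        )
    counts = LeafletCounts(n_dspc=n_dspc, n_chol=n_chol, n_l5=n_l5)
    return {Leaflet.UPPER: counts, Leaflet.LOWER: LeafletCounts(n_dspc, n_chol, n_l5)}


def assign_protonation(n_l5: int, fraction: float = 0.5, seed: int = 0) -> list[Protonation]:
    """Randomly ordered protonation labels with round-half-up protonated count."""
    if n_l5 < 0:
        raise CompositionError("n_l5 must be non-negative")
    n_prot = _round_half_up(fraction * n_l5)
    labels = [Protonation.PROTONATED] * n_prot + [Protonation.NEUTRAL] * (n_l5 - n_prot)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_l5)
    return [labels[i] for i in order]


def assign_protonation_per_leaflet(
    n_per_leaflet: dict[Leaflet, int], fraction: float = 0.5, seed: int = 0
) -> dict[Leaflet, list[Protonation]]:
    """Per-leaflet labels with the protonated count balanced across leaflets.

    The global protonated count is round-half-up of ``fraction`` times the
    total; it is split across leaflets proportionally, remainder (the
    protonated excess) going to the upper leaflet first.
    """
    total = sum(n_per_leaflet.values())
    n_prot_total = _round_half_up(fraction * total)
    out: dict[Leaflet, list[Protonation]] = {}
    remaining = n_prot_total
    leaflets = sorted(n_per_leaflet, key=lambda lf: (lf is not Leaflet.UPPER, lf.value))
    quotas: dict[Leaflet, int] = {}
    for k, lf in enumerate(leaflets):
        # even split, ceiling first so the protonated excess lands upper-first
        q = min(n_per_leaflet[lf], -(-remaining // (len(leaflets) - k)))
        quotas[lf] = q
        remaining -= q
    for lf in leaflets:  # mop up if an earlier leaflet lacked room
        if remaining <= 0:
            break
        take = min(n_per_leaflet[lf] - quotas[lf], remaining)
        quotas[lf] += take
        remaining -= take
    rng = np.random.default_rng(seed)
    for lf in leaflets:
        n_here = n_per_leaflet[lf]
        labels = [Protonation.PROTONATED] * quotas[lf] + [Protonation.NEUTRAL] * (
            n_here - quotas[lf]
        )
        order = rng.permutation(n_here)
        out[lf] = [labels[i] for i in order]
    return out


def select_replacements(
    system: MolecularSystem,
    counts: dict[Leaflet, int],
    seed: int = 0,
    replaceable: Species = Species.DSPC,
) -> list[int]:
    """Randomly select molecule ids of the replaceable species, per leaflet.

    Reproducible under *seed*; distinct seeds give independent replicates.
    """
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for leaflet in sorted(counts, key=lambda lf: lf.value):
        want = counts[leaflet]
        pool = [
            m.molecule_id
            for m in system.molecules
            if m.species is replaceable and m.leaflet is leaflet
        ]
        if want > len(pool):
            raise SelectionError(
                f"need {want} {replaceable} molecules in {leaflet.value} leaflet, "
                f"only {len(pool)} available"
            )
        if want:
            picks = rng.choice(len(pool), size=want, replace=False)
            chosen.extend(pool[i] for i in picks)
    return chosen
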