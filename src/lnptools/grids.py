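"""Volumetric repulsive grid potentials.

A grid potential is a scalar field in [0, 1] sampled on a regular lattice,
shaped like the bounding cylinder of the lipid to be inserted: 1 strictly
inside the cylinder, falling to 0 over one smoothing length outside it.  The
energy of an atom at position x is k * V(x) with V the trilinear
interpolation of the field, so the force is -k * grad V.

The falloff uses a shifted, truncated Gaussian with sigma = resolution / 2:
(exp(-d^2 / 2 sigma^2) - exp(-2)) / (1 - exp(-2)) for d < resolution, zero
beyond, where d is the distance outside the cylinder surface.  This honors
both the stated Gaussian smoothing scale and the requirement that the field
vanish exactly one smoothing length outside the cylinder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .species import Leaflet, Species
from .system import MolecularSystem, Molecule
from .template import LipidTemplate


@dataclass
class GridPotential:
    origin: np.ndarray          # (3,) lattice origin, Angstrom
    spacing: float              # node spacing, Angstrom
    dims: tuple[int, int, int]  # nodes per axis
    values: np.ndarray          # (nx, ny, nz) field in [0, 1]
    force_constant: float = 1.0
    site_axis: np.ndarray | None = None    # unit head-to-tail direction
    axis_point: np.ndarray | None = None   # a point on the cylinder axis (center)
    cylinder_radius: float = 0.0
    cylinder_half_length: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise GeometryError("grid spacing must be positive")
        if self.values.shape != tuple(self.dims):
            raise GeometryError(
                f"values shape {self.values.shape} does not match dims {self.dims}"
            )
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise GeometryError("grid values must lie in [0, 1]")

    @property
    def extent(self) -> np.ndarray:
        """(3,) upper corner of the lattice."""
        return self.origin + (np.array(self.dims) - 1) * self.spacing

    # ------------------------------------------------------------------
    def interpolate(
        self, points: np.ndarray, want_gradient: bool = True
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Trilinear field values and analytic gradients at (N, 3) points.

        Outside the lattice both value and gradient are zero (the field is
        built with a zero-valued margin, so the function stays continuous).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        vals = np.zeros(n)
        grads = np.zeros((n, 3)) if want_gradient else None
        rel = (pts - self.origin) / self.spacing
        dims = np.array(self.dims)
        inside = np.all((rel >= 0) & (rel <= dims - 1), axis=1)
        if not inside.any():
            return vals, grads
        r = rel[inside]
        i0 = np.minimum(r.astype(int), dims - 2)
        t = r - i0
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
        V = self.values
        c000 = V[ix, iy, iz]
        c100 = V[ix + 1, iy, iz]
        c010 = V[ix, iy + 1, iz]
        c110 = V[ix + 1, iy + 1, iz]
        c001 = V[ix, iy, iz + 1]
        c101 = V[ix + 1, iy, iz + 1]
        c011 = V[ix, iy + 1, iz + 1]
        c111 = V[ix + 1, iy + 1, iz + 1]
        # interpolate along x, then y, then z
        c00 = c000 + tx * (c100 - c000)
        c01 = c001 + tx * (c101 - c001)
        c10 = c010 + tx * (c110 - c010)
        c11 = c011 + tx * (c111 - c011)
        c0 = c00 + ty * (c10 - c00)
        c1 = c01 + ty * (c11 - c01)
        vals[inside] = c0 + tz * (c1 - c0)
        if not want_gradient:
            return vals, None
        # analytic partials of the trilinear form
        dx00 = c100 - c000
        dx01 = c101 - c001
        dx10 = c110 - c010
        dx11 = c111 - c011
        dx0 = dx00 + ty * (dx10 - dx00)
        dx1 = dx01 + ty * (dx11 - dx01)
        gx = (dx0 + tz * (dx1 - dx0)) / self.spacing
        gy = ((c10 - c00) + tz * ((c11 - c01) - (c10 - c00))) / self.spacing
        gz = (c1 - c0) / self.spacing
        g = np.zeros((inside.sum(), 3))
        g[:, 0] = gx
        g[:, 1] = gy
        g[:, 2] = gz
        grads[inside] = g
        return vals, grads

    def value_at(self, point) -> float:
        v, _ = self.interpolate(np.asarray(point, dtype=float).reshape(1, 3))
        return float(v[0])

    def outward_radial(self, points: np.ndarray) -> np.ndarray:
        """Unit directions pointing radially away from the cylinder axis.

        Used by the relaxer to escape the flat (value = 1) plateau inside the
        cylinder, where the field gradient vanishes.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self.axis_point
        axial = rel @ self.site_axis
        radial = rel - np.outer(axial, self.site_axis)
        norms = np.linalg.norm(radial, axis=1)
        out = np.zeros_like(pts)
        ok = norms > 1e-9
        out[ok] = radial[ok] / norms[ok, None]
        # points exactly on the axis: push along an arbitrary perpendicular
        if (~ok).any():
            perp = np.cross(self.site_axis, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(self.site_axis, [0.0, 1.0, 0.0])
            out[~ok] = perp / np.linalg.norm(perp)
        return out


def cylinder_field(
    points: np.ndarray,
    center: np.ndarray,
    axis: np.ndarray,
    radius: float,
    half_length: float,
    resolution: float,
) -> np.ndarray:
    """Smoothed cylinder indicator evaluated at (N, 3) points."""
    sigma = resolution / 2.0
    rel = points - center
    s = rel @ axis
    radial = rel - np.outer(s, axis)
    rho = np.linalg.norm(radial, axis=1)
    d_r = np.maximum(rho - radius, 0.0)
    d_a = np.maximum(np.abs(s) - half_length, 0.0)
    d = np.sqrt(d_r ** 2 + d_a ** 2)
    floor = np.exp(-2.0)
    raw = (np.exp(-(d ** 2) / (2.0 * sigma ** 2)) - floor) / (1.0 - floor)
    return np.clip(np.where(d >= resolution, 0.0, raw), 0.0, 1.0)


def site_axis_of(
    system: MolecularSystem, mol: Molecule, head_table: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(head position, unit head-to-tail axis) of a site molecule.

    The axis runs from the head-reference atom toward the centroid of the
    molecule's remaining heavy atoms; its sign is fixed so the tail end points
    toward the membrane core (down for the upper leaflet, up for the lower).
    """
    hi = system.head_atom_index(mol, head_table)
    head = system.positions[hi].copy()
    idx = system.indices_of(mol.atom_ids)
    heavy = np.array([i for i in idx if str(system.elements[i]).upper() != "H"])
    others = heavy[heavy != hi]
    if len(others) == 0:
        raise GeometryError(f"molecule {mol.molecule_id}: no tail atoms to define an axis")
    tail_centroid = system.positions[others].mean(axis=0)
    v = tail_centroid - head
    norm = np.linalg.norm(v)
    if norm < 1e-6:
        raise GeometryError(f"molecule {mol.molecule_id}: degenerate head-to-tail axis")
    v = v / norm
    if mol.leaflet is Leaflet.UPPER and v[2] > 0:
        v = -v
    elif mol.leaflet is Leaflet.LOWER and v[2] < 0:
        v = -v
    return head, v


def build_grid_potential(
    site_molecule: Molecule,
    system: MolecularSystem,
    template: LipidTemplate,
    spacing: float = 0.8,
    resolution: float = 6.0,
    pad: float = 1.0,
    force_constant: float = 1.0,
) -> GridPotential:
    """Cylindrical repulsive grid at a selected lipid's site.

    The cylinder axis follows the site lipid's head-to-tail direction (head
    end toward water, tails toward the hydrophobic core); its radius and
    length are the template's bounding cylinder plus *pad*.  Node spacing is
    exactly *spacing*; the field edge is smoothed over *resolution*.
    """
    from .species import Protonation

    head, axis = site_axis_of(system, site_molecule)
    variant = (
        Protonation.PROTONATED
        if Protonation.PROTONATED in template.variants
        else next(iter(template.variants))
    )
    t_radius, t_length = template.bounding_cylinder(variant)
    radius = t_radius + pad
    length = t_length + 2 * pad
    half = length / 2.0
    center = head + axis * (half - pad)

    margin = resolution + spacing
    # tight per-axis extent of the tilted cylinder
    half_extent = (
        half * np.abs(axis)
        + radius * np.sqrt(np.clip(1.0 - axis ** 2, 0.0, 1.0))
        + margin
    )
    lo = center - half_extent
    hi = center + half_extent
    dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    axes = [lo[i] + spacing * np.arange(dims[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    vals = cylinder_field(nodes, center, axis, radius, half, resolution).reshape(dims)
    return GridPotential(
        origin=lo,
        spacing=spacing,
        dims=dims,
        values=vals,
        force_constant=force_constant,
        site_axis=axis,
        axis_point=center,
        cylinder_radius=radius,
        cylinder_half_length=half,
    )


def grid_force(grid: GridPotential, position) -> np.ndarray:
    """Force -k * grad V(x); zero outside the lattice extent."""
    pts = np.atleast_2d(np.asarray(position, dtype=float))
    _, grads = grid.interpolate(pts)
    f = -grid.force_constant * grads
    return f[0] if np.asarray(position).ndim == 1 else f
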