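"""Quantitative bilayer characterization.

All metrics operate on a :class:`~lnptools.system.Trajectory`, recenter z on
the per-frame midplane (the mean z of the phospholipid phosphorus atoms),
and use minimum-image distances in the membrane (x-y) plane where lateral
geometry is involved.  Profiles are accumulated over frames; replicate
averaging helpers compute mean +/- standard deviation across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .errors import GeometryError, SelectionError
from .geometry import lateral_distance_matrix, minimum_image_distance_matrix
from .species import Leaflet, Protonation, Species
from .system import MolecularSystem, Trajectory, midplane_z

# ---------------------------------------------------------------------------
# selections


def atom_selector(
    species: Species | None = None,
    protonation: Protonation | None = None,
    name: str | None = None,
    element: str | None = None,
):
    """Build an atom predicate: system -> array of atom indices."""

    def _select(system: MolecularSystem) -> np.ndarray:
        idx: list[int] = []
        for mol in system.molecules:
            if species is not None and mol.species is not species:
                continue
            if protonation is not None and mol.protonation is not protonation:
                continue
            for aid in mol.atom_ids:
                i = system.index_of(aid)
                if name is not None and str(system.atom_names[i]).strip() != name:
                    continue
                if element is not None and str(system.elements[i]).upper() != element.upper():
                    continue
                idx.append(i)
        return np.array(idx, dtype=np.intp)

    return _select


def molecule_selector(
    species: Species | None = None,
    protonation: Protonation | None = None,
    leaflet: Leaflet | None = None,
):
    """Build a molecule predicate: system -> list of molecules."""

    def _select(system: MolecularSystem):
        out = []
        for mol in system.molecules:
            if species is not None and mol.species is not species:
                continue
            if protonation is not None and mol.protonation is not protonation:
                continue
            if leaflet is not None and mol.leaflet is not leaflet:
                continue
            out.append(mol)
        return out

    return _select


# ---------------------------------------------------------------------------
# result containers


@dataclass
class DensityProfile:
    bin_centers: np.ndarray      # z relative to the midplane, Angstrom
    scaled_counts: np.ndarray    # max-normalized counts
    raw_counts: np.ndarray
    slice_width: float
    n_samples: int

    @property
    def is_empty(self) -> bool:
        return self.n_samples == 0

    @property
    def peak_z(self) -> float:
        if self.is_empty:
            raise ValueError("empty density profile has no peak")
        return float(self.bin_centers[int(np.argmax(self.raw_counts))])


@dataclass
class CrossingAngleHistogram:
    bin_edges: np.ndarray        # 26 edges over cos(theta) in [-1, 1]
    probabilities: np.ndarray    # 25 values summing to 1
    n_pairs: int

    @property
    def is_empty(self) -> bool:
        return self.n_pairs == 0


@dataclass
class LateralRDF:
    r_centers: np.ndarray
    g_values: np.ndarray
    group_pair: tuple[str, str]
    n_reference: int

    @property
    def is_empty(self) -> bool:
        return self.n_reference == 0


@dataclass(frozen=True)
class OrientationRecord:
    molecule_id: int
    frame: int
    theta_deg: float


@dataclass
class OrderParameterResult:
    group: str
    S: float
    n_samples: int


@dataclass
class PartitionCoefficient:
    n_surface: int
    n_core: int

    @property
    def ratio(self) -> float | None:
        if self.n_surface == 0:
            return None  # undefined-ratio sentinel; counts still reported
        return self.n_core / self.n_surface


@dataclass
class ClusterLabels:
    labels: np.ndarray           # -1 = noise
    eps: float
    min_points: int

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))


@dataclass
class ProjectionMap:
    plane: str                   # "xz", "xy-upper", "xy-lower"
    x_edges: np.ndarray
    y_edges: np.ndarray
    histogram: np.ndarray        # mass-weighted counts
    total_mass: float = 0.0


# ---------------------------------------------------------------------------
# metrics


def scaled_mass_density(
    traj: Trajectory, selection, slice_width: float = 1.4
) -> DensityProfile:
    """z-histogram of selected atoms around the midplane, max scaled to one."""
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    lz = float(max(b[2] for b in traj.boxes))
    # grid centered on the midplane (a bin center at z = 0), so mirror-symmetric
    # populations land symmetrically in the slices
    n_half = int(np.ceil(lz / 2.0 / slice_width))
    edges = slice_width * (np.arange(-n_half, n_half + 1) + 0.5)
    nbins = len(edges) - 1
    counts = np.zeros(nbins)
    n_total = 0
    for k in range(traj.n_frames):
        sys_k = traj.frame_system(k)
        idx = selection(sys_k)
        if len(idx) == 0:
            continue
        z = sys_k.positions[idx, 2] - midplane_z(sys_k)
        h, _ = np.histogram(z, bins=edges)
        counts += h
        n_total += len(idx)
    centers = 0.5 * (edges[:-1] + edges[1:])
    scaled = counts / counts.max() if counts.max() > 0 else counts
    return DensityProfile(
        bin_centers=centers,
        scaled_counts=scaled,
        raw_counts=counts,
        slice_width=slice_width,
        n_samples=n_total,
    )


def _tail_vector(system: MolecularSystem, mol, tail_names: tuple[str, str]) -> np.ndarray:
    i0 = system.named_atom_index(mol, tail_names[0])
    i1 = system.named_atom_index(mol, tail_names[1])
    v = system.positions[i1] - system.positions[i0]
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GeometryError(f"molecule {mol.molecule_id}: zero-length tail axis")
    return v / n, 0.5 * (system.positions[i0] + system.positions[i1])


def crossing_angle_distribution(
    traj: Trajectory,
    species: Species = Species.L5,
    group: Protonation | None = None,
    tail_atoms: tuple[str, str] | None = None,
    cutoff: float = 10.0,
    bins: int = 25,
) -> CrossingAngleHistogram:
    """Distribution of cos(crossing angle) between nearby unbranched tails.

    For every same-group molecule pair whose tail midpoints are within
    *cutoff* in the membrane plane (minimum image), the signed cosine of the
    angle between the two unit tail axes is accumulated into *bins* over
    [-1, 1] and normalized to a probability distribution.
    """
    tail_names = tail_atoms or chem.UNBRANCHED_TAIL[species]
    edges = np.linspace(-1.0, 1.0, bins + 1)
    counts = np.zeros(bins)
    n_pairs = 0
    for k in range(traj.n_frames):
        sys_k = traj.frame_system(k)
        mols = molecule_selector(species=species, protonation=group)(sys_k)
        if len(mols) < 2:
            continue
        axes, mids = [], []
        for mol in mols:
            try:
                v, m = _tail_vector(sys_k, mol, tail_names)
            except GeometryError:
                continue  # marker/partial molecules carry no tail
            axes.append(v)
            mids.append(m)
        if len(axes) < 2:
            continue
        axes = np.array(axes)
        mids = np.array(mids)
        dist = lateral_distance_matrix(mids[:, :2], mids[:, :2], sys_k.box[:2])
        iu, ju = np.triu_indices(len(axes), k=1)
        close = dist[iu, ju] <= cutoff
        if not close.any():
            continue
        cosv = np.einsum("ij,ij->i", axes[iu[close]], axes[ju[close]])
        cosv = np.clip(cosv, -1.0, 1.0)
        h, _ = np.histogram(cosv, bins=edges)
        # cos = +1 falls in the last bin, not out of range
        counts += h
        n_pairs += int(close.sum())
    probs = counts / counts.sum() if counts.sum() > 0 else counts
    return CrossingAngleHistogram(bin_edges=edges, probabilities=probs, n_pairs=n_pairs)


def _centroids(system: MolecularSystem, mols) -> np.ndarray:
    pts = []
    for mol in mols:
        idx = system.indices_of(mol.atom_ids)
        heavy = idx[[str(system.elements[i]).upper() != "H" for i in idx]]
        pts.append(system.positions[heavy].mean(axis=0))
    return np.array(pts)


def lateral_rdf(
    traj: Trajectory,
    group_a,
    group_b=None,
    dr: float = 1.0,
    r_max: float | None = None,
) -> LateralRDF:
    """Two-dimensional radial distribution function in the membrane plane.

    Distances between per-molecule heavy-atom centroids are computed in x-y
    only (minimum image); both leaflets are pooled, so molecules sitting on
    top of each other across leaflets produce density at zero distance.
    Normalization divides by the ideal-gas annulus count 2*pi*r*dr*rho_b per
    reference molecule, with rho_b from the instantaneous in-plane box area;
    frames are averaged with equal weight.
    """
    same = group_b is None
    group_b = group_a if same else group_b
    label_a = getattr(group_a, "__name__", "group_a")
    g_frames = []
    n_ref_total = 0
    r_edges = None
    for k in range(traj.n_frames):
        sys_k = traj.frame_system(k)
        mols_a = group_a(sys_k)
        mols_b = group_b(sys_k)
        identical = same or [m.molecule_id for m in mols_a] == [
            m.molecule_id for m in mols_b
        ]
        if len(mols_a) < 1 or len(mols_b) < (2 if identical else 1):
            continue
        box_xy = sys_k.box[:2]
        if r_edges is None:
            rmax = r_max if r_max is not None else float(min(box_xy)) / 2.0
            r_edges = dr * np.arange(0, int(np.floor(rmax / dr)) + 1)
        ca = _centroids(sys_k, mols_a)
        cb = ca if identical else _centroids(sys_k, mols_b)
        dist = lateral_distance_matrix(ca[:, :2], cb[:, :2], box_xy)
        if identical:
            np.fill_diagonal(dist, np.inf)
        h, _ = np.histogram(dist.ravel(), bins=r_edges)
        area = float(box_xy[0] * box_xy[1])
        rho_b = (len(mols_b) - (1 if identical else 0)) / area
        r_lo = r_edges[:-1]
        shell = np.pi * (r_edges[1:] ** 2 - r_lo ** 2)
        ideal = shell * rho_b * len(mols_a)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(ideal > 0, h / ideal, 0.0)
        g_frames.append(g)
        n_ref_total += len(mols_a)
    if not g_frames:
        return LateralRDF(
            r_centers=np.array([]), g_values=np.array([]),
            group_pair=(label_a, label_a if same else "group_b"), n_reference=0,
        )
    g_mean = np.mean(g_frames, axis=0)
    centers = 0.5 * (r_edges[:-1] + r_edges[1:])
    return LateralRDF(
        r_centers=centers,
        g_values=g_mean,
        group_pair=(label_a, label_a if same else "group_b"),
        n_reference=n_ref_total,
    )


def orientation_angles(
    traj: Trajectory,
    species: Species,
    protonation: Protonation | None = None,
    axis_table: dict | None = None,
) -> list[OrientationRecord]:
    """Per-molecule, per-frame tilt angle of the species axis vs. the leaflet normal.

    The axis runs from the tail-reference centre of mass to the head-reference
    centre of mass; it is measured against +z for upper-leaflet molecules and
    -z for lower-leaflet ones, so an upright lipid scores ~0 degrees in both.
    """
    table = axis_table or chem.ORIENTATION_AXES
    if species not in table:
        raise SelectionError(f"no orientation-axis atom table for {species}")
    tail_names, head_names = table[species]
    records: list[OrientationRecord] = []
    for k in range(traj.n_frames):
        sys_k = traj.frame_system(k)
        masses = sys_k.masses()
        for mol in sys_k.molecules:
            if mol.species is not species:
                continue
            if protonation is not None and mol.protonation is not protonation:
                continue
            try:
                t_idx = [sys_k.named_atom_index(mol, n) for n in tail_names]
                h_idx = [sys_k.named_atom_index(mol, n) for n in head_names]
            except GeometryError as exc:
                if len(mol.atom_ids) > 1:
                    raise SelectionError(str(exc))
                continue  # single-atom markers carry no axis
            t_com = np.average(sys_k.positions[t_idx], axis=0, weights=masses[t_idx])
            h_com = np.average(sys_k.positions[h_idx], axis=0, weights=masses[h_idx])
            v = h_com - t_com
            n = np.linalg.norm(v)
            if n < 1e-9:
                continue
            normal = np.array([0.0, 0.0, -1.0 if mol.leaflet is Leaflet.LOWER else 1.0])
            cos_t = float(np.clip((v / n) @ normal, -1.0, 1.0))
            records.append(
                OrientationRecord(mol.molecule_id, k, float(np.degrees(np.arccos(cos_t))))
            )
    return records


def modified_order_parameter(records, group: str = "") -> OrderParameterResult:
    """Whole-lipid orientational order: S = <(3 cos^2 theta - 1) / 2>.

    The second-Legendre average over molecules and frames: 1 for a perfectly
    upright population, 0 for an isotropic one, -0.5 for in-plane axes.
    """
    thetas = np.array(
        [r.theta_deg if isinstance(r, OrientationRecord) else float(r) for r in records]
    )
    if thetas.size == 0:
        raise ValueError("modified_order_parameter requires at least one record")
    c = np.cos(np.radians(thetas))
    s = float(np.mean(1.5 * c ** 2 - 0.5))
    return OrderParameterResult(group=group, S=s, n_samples=int(thetas.size))


def project_coordinates(
    traj: Trajectory,
    selection,
    plane: str,
    leaflet: Leaflet | None = None,
    bin_size: float = 1.0,
) -> ProjectionMap:
    """Mass-weighted 2-D histogram of selected atoms in the x-z or x-y plane.

    For x-y projections the selection can be restricted to one leaflet (the
    leaflet of the atom's parent molecule).  z is midplane-centered.
    """
    if plane not in ("xz", "xy-upper", "xy-lower", "xy"):
        raise ValueError(f"unknown projection plane: {plane!r}")
    if plane in ("xy-upper", "xy-lower"):
        leaflet = Leaflet.UPPER if plane == "xy-upper" else Leaflet.LOWER
    box = traj.topology.box
    if plane == "xz":
        lim0, lim1 = box[0], box[2]
        e0 = bin_size * np.arange(0, int(np.ceil(lim0 / bin_size)) + 1)
        e1 = -lim1 / 2 + bin_size * np.arange(0, int(np.ceil(lim1 / bin_size)) + 1)
    else:
        e0 = bin_size * np.arange(0, int(np.ceil(box[0] / bin_size)) + 1)
        e1 = bin_size * np.arange(0, int(np.ceil(box[1] / bin_size)) + 1)
    hist = np.zeros((len(e0) - 1, len(e1) - 1))
    total_mass = 0.0
    for k in range(traj.n_frames):
        sys_k = traj.frame_system(k)
        idx = selection(sys_k)
        if len(idx) == 0:
            continue
        if leaflet is not None:
            keep = []
            for i in idx:
                mid = sys_k.molecule_of_atom(int(sys_k.atom_ids[i]))
                if sys_k.molecule(mid).leaflet is leaflet:
                    keep.append(i)
            idx = np.array(keep, dtype=np.intp)
            if len(idx) == 0:
                continue
        masses = sys_k.masses()[idx]
        pos = sys_k.positions[idx]
        if plane == "xz":
            a = np.mod(pos[:, 0], box[0])
            b = pos[:, 2] - midplane_z(sys_k)
        else:
            a = np.mod(pos[:, 0], box[0])
            b = np.mod(pos[:, 1], box[1])
        h, _, _ = np.histogram2d(a, b, bins=(e0, e1), weights=masses)
        hist += h
        total_mass += float(masses.sum())
    return ProjectionMap(
        plane=plane, x_edges=e0, y_edges=e1, histogram=hist, total_mass=total_mass
    )


def cholesterol_partitioning(
    traj: Trajectory,
    surface_cutoff: float = 10.0,
    water_boundaries: tuple[float, float] | None = None,
    hydroxyl_name: str = "O3",
) -> PartitionCoefficient:
    """Cholesterol core/surface partition coefficient.

    Per frame, the water boundary on each side is the innermost z of the bulk
    water slab (smallest |z - midplane| among water oxygens on that side); a
    cholesterol is *surface* when its hydroxyl oxygen lies within
    *surface_cutoff* (in z) of the nearer boundary, else *core*.  When the
    trajectory carries no water, explicit midplane-relative boundary z values
    may be supplied as ``water_boundaries=(upper, lower)`` with lower < 0.
    The coefficient is total core / total surface over all frames; with no
    surface cholesterol it is undefined and reported as ``None`` alongside
    the counts.
    """
    n_surface = 0
    n_core = 0
    for k in range(traj.n_frames):
        sys_k = traj.frame_system(k)
        mid = midplane_z(sys_k)
        if water_boundaries is not None:
            z_up, z_lo = water_boundaries
        else:
            wz = []
            for mol in sys_k.molecules_of(Species.WATER):
                for aid in mol.atom_ids:
                    i = sys_k.index_of(aid)
                    if str(sys_k.elements[i]).upper() == "O":
                        wz.append(sys_k.positions[i, 2] - mid)
            wz = np.array(wz)
            if wz.size == 0:
                raise GeometryError(
                    "no water present: supply water_boundaries=(upper_z, lower_z)"
                )
            above, below = wz[wz > 0], wz[wz <= 0]
            if above.size == 0 or below.size == 0:
                raise GeometryError("water found on only one side of the bilayer")
            z_up, z_lo = float(above.min()), float(below.max())
        for mol in sys_k.molecules_of(Species.CHOL):
            z = sys_k.positions[sys_k.named_atom_index(mol, hydroxyl_name), 2] - mid
            boundary = z_up if z > 0 else z_lo
            if abs(boundary - z) <= surface_cutoff or abs(z) >= abs(boundary):
                n_surface += 1
            else:
                n_core += 1
    return PartitionCoefficient(n_surface=n_surface, n_core=n_core)


def cluster_aggregates(
    points: np.ndarray,
    box: np.ndarray,
    eps: float = 5.0,
    min_points: int = 50,
) -> ClusterLabels:
    """Density-based clustering (DBSCAN) under minimum-image distances.

    A point is a core point when at least *min_points* points (itself
    included) fall within *eps*; clusters are the density-connected sets and
    everything else is noise (label -1).
    """
    from sklearn.cluster import DBSCAN

    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return ClusterLabels(labels=np.array([], dtype=int), eps=eps, min_points=min_points)
    if not np.all(np.isfinite(points)):
        raise ValueError("cluster_aggregates requires finite points")
    dist = minimum_image_distance_matrix(points, np.asarray(box, dtype=float))
    labels = DBSCAN(eps=eps, min_samples=min_points, metric="precomputed").fit_predict(dist)
    return ClusterLabels(labels=labels, eps=eps, min_points=min_points)


def analysis_window(traj: Trajectory, fraction: float = 1 / 3, last_n: int | None = None) -> Trajectory:
    """Trailing analysis window: by default the last third of the frames,
    mirroring production runs analysed over their final stretch."""
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    if last_n is None:
        last_n = int(np.ceil(traj.n_frames * fraction))
    if last_n < 1 or last_n > traj.n_frames:
        raise ValueError(f"window of {last_n} frames invalid for {traj.n_frames}-frame trajectory")
    return Trajectory(
        topology=traj.topology,
        frames=traj.frames[-last_n:],
        boxes=traj.boxes[-last_n:],
    )


def replicate_mean(values) -> tuple[float, float]:
    """Mean and standard deviation across replicate scalar results."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))
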