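"""Cholesterol partitioning and density-based aggregate detection."""

import numpy as np
import pytest

import lnptools as lp
from lnptools import analysis as an
from lnptools.species import Leaflet, Protonation, Species
from lnptools.system import AtomRecord, MolecularSystem, Molecule, Trajectory


def _chol_system(chol_zs, water_zs=(33.0, -33.0), box=(60.0, 60.0, 90.0)):
    """Cholesterol hydroxyls at given midplane-relative z, plus water planes."""
    mid = 45.0
    atoms = [
        AtomRecord(1, "P", "P", 1, "DSPC", (1.0, 1.0, mid + 20)),
        AtomRecord(2, "P", "P", 2, "DSPC", (2.0, 2.0, mid - 20)),
    ]
    mols = [
        Molecule(1, Species.DSPC, atom_ids=[1]),
        Molecule(2, Species.DSPC, atom_ids=[2]),
    ]
    aid, mol_id = 3, 3
    for z in chol_zs:
        atoms.append(AtomRecord(aid, "O3", "O", mol_id, "CHOL", (5.0, 5.0, mid + z)))
        mols.append(Molecule(mol_id, Species.CHOL, atom_ids=[aid]))
        aid += 1
        mol_id += 1
    for zw in water_zs:
        atoms.append(AtomRecord(aid, "OH2", "O", mol_id, "TIP3", (9.0, 9.0, mid + zw)))
        mols.append(Molecule(mol_id, Species.WATER, atom_ids=[aid]))
        aid += 1
        mol_id += 1
    return MolecularSystem(atoms=atoms, bonds=[], molecules=mols, box=box)


def test_all_near_boundary_is_zero_ratio():
    # hydroxyls 2 A below the water boundary on each side
    sys0 = _chol_system([31.0, -31.0])
    part = an.cholesterol_partitioning(Trajectory.from_system(sys0))
    assert part.n_core == 0
    assert part.ratio == 0.0


def test_ratio_arithmetic():
    part = an.PartitionCoefficient(n_surface=100, n_core=2)
    assert part.ratio == pytest.approx(0.02)


def test_no_surface_is_undefined_sentinel():
    sys0 = _chol_system([0.0, 1.0])
    part = an.cholesterol_partitioning(Trajectory.from_system(sys0))
    assert part.n_surface == 0 and part.n_core == 2
    assert part.ratio is None


def test_explicit_boundaries_without_water():
    sys0 = _chol_system([25.0, 0.0], water_zs=())
    part = an.cholesterol_partitioning(
        Trajectory.from_system(sys0), water_boundaries=(33.0, -33.0)
    )
    assert (part.n_surface, part.n_core) == (1, 1)


def test_classification_matches_bruteforce_oracle():
    rng = np.random.default_rng(41)
    zs = rng.uniform(-30, 30, 60)
    sys0 = _chol_system(zs)
    part = an.cholesterol_partitioning(Trajectory.from_system(sys0))
    # oracle: per-molecule z-distance to the boundary on its own side
    n_surf = 0
    for z in zs:
        boundary = 33.0 if z > 0 else -33.0
        if abs(boundary - z) <= 10.0:
            n_surf += 1
    assert part.n_surface == n_surf
    assert part.n_core == len(zs) - n_surf


# ---------------------------------------------------------------------------
# DBSCAN aggregates


BOX = np.array([100.0, 100.0, 90.0])

from tests_support_oracles import brute_force_dbscan, same_partition as _same_partition


def test_threshold_edge_all_noise():
    pts = np.tile([[50.0, 50.0, 45.0]], (49, 1))
    out = an.cluster_aggregates(pts, BOX, eps=5.0, min_points=50)
    assert np.all(out.labels == -1)
    out2 = an.cluster_aggregates(np.tile([[50.0, 50.0, 45.0]], (50, 1)), BOX)
    assert out2.n_clusters == 1


def test_single_blob_is_one_cluster():
    rng = np.random.default_rng(5)
    pts = np.array([50.0, 50.0, 45.0]) + rng.normal(0, 1.0, (60, 3))
    pts = np.clip(pts, None, None)
    out = an.cluster_aggregates(pts, BOX)
    assert out.n_clusters == 1
    assert np.all(out.labels == 0)
    assert _same_partition(out.labels, brute_force_dbscan(pts, BOX, 5.0, 50))


def test_two_separated_blobs_are_two_clusters():
    rng = np.random.default_rng(6)
    a = np.array([30.0, 30.0, 45.0]) + rng.normal(0, 1.0, (60, 3))
    b = np.array([70.0, 70.0, 45.0]) + rng.normal(0, 1.0, (60, 3))
    pts = np.vstack([a, b])
    out = an.cluster_aggregates(pts, BOX)
    assert out.n_clusters == 2
    assert _same_partition(out.labels, brute_force_dbscan(pts, BOX, 5.0, 50))


def test_blob_split_across_periodic_boundary():
    rng = np.random.default_rng(8)
    pts = rng.normal(0, 1.5, (60, 3)) + np.array([0.0, 50.0, 45.0])
    pts[:, 0] = np.mod(pts[:, 0], BOX[0])  # halves at x~0 and x~100
    out = an.cluster_aggregates(pts, BOX)
    assert out.n_clusters == 1


def test_random_instances_match_oracle():
    rng = np.random.default_rng(9)
    for trial in range(15):
        n_blobs = rng.integers(1, 4)
        pts = []
        for _ in range(n_blobs):
            c = rng.uniform(10, 90, 3)
            pts.append(c + rng.normal(0, rng.uniform(0.8, 2.5), (rng.integers(20, 70), 3)))
        pts.append(rng.uniform(0, 90, (rng.integers(5, 30), 3)))  # sparse noise
        pts = np.vstack(pts)[:200]
        eps, mp = 5.0, int(rng.integers(10, 60))
        got = an.cluster_aggregates(pts, BOX, eps=eps, min_points=mp)
        ref = brute_force_dbscan(pts, BOX, eps, mp)
        assert _same_partition(got.labels, ref)
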