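"""Orientation angles, order parameter, and crossing-angle distributions."""

import numpy as np
import pytest

import lnptools as lp
from lnptools import analysis as an
from lnptools.analysis import OrientationRecord
from lnptools.species import Leaflet, Protonation, Species
from lnptools.system import AtomRecord, MolecularSystem, Molecule, Trajectory


def _l5_pair_system(tails, midpoints, box=(60.0, 60.0, 90.0), leaflet=Leaflet.UPPER):
    """Minimal L5 molecules with a C1B->C4B tail along the given unit vectors."""
    atoms = [
        AtomRecord(1, "P", "P", 1, "DSPC", (1.0, 1.0, 65.0)),
        AtomRecord(2, "P", "P", 2, "DSPC", (2.0, 2.0, 25.0)),
    ]
    mols = [
        Molecule(1, Species.DSPC, atom_ids=[1]),
        Molecule(2, Species.DSPC, atom_ids=[2]),
    ]
    aid, mid = 3, 3
    for t, m in zip(tails, midpoints):
        t = np.asarray(t, dtype=float)
        m = np.asarray(m, dtype=float)
        p0 = m - 2.0 * t
        p1 = m + 2.0 * t
        atoms += [
            AtomRecord(aid, "C1B", "C", mid, "L5P", tuple(p0)),
            AtomRecord(aid + 1, "C4B", "C", mid, "L5P", tuple(p1)),
        ]
        mols.append(
            Molecule(mid, Species.L5, Protonation.PROTONATED, leaflet,
                     atom_ids=[aid, aid + 1])
        )
        aid += 2
        mid += 1
    return MolecularSystem(atoms=atoms, bonds=[], molecules=mols, box=box)


def _axis_system(axis, leaflet):
    """One L5 molecule with tail anchors and head nitrogen along the axis."""
    axis = np.asarray(axis, dtype=float)
    head = np.array([10.0, 10.0, 45.0]) + 8.0 * axis
    anchor = np.array([10.0, 10.0, 45.0])
    atoms = [
        AtomRecord(1, "P", "P", 1, "DSPC", (1.0, 1.0, 65.0)),
        AtomRecord(2, "P", "P", 2, "DSPC", (2.0, 2.0, 25.0)),
        AtomRecord(3, "N", "N", 3, "L5P", tuple(head)),
        AtomRecord(4, "O1", "O", 3, "L5P", tuple(anchor + [0.5, 0, 0])),
        AtomRecord(5, "O2", "O", 3, "L5P", tuple(anchor - [0.5, 0, 0])),
    ]
    mols = [
        Molecule(1, Species.DSPC, atom_ids=[1]),
        Molecule(2, Species.DSPC, atom_ids=[2]),
        Molecule(3, Species.L5, Protonation.PROTONATED, leaflet, atom_ids=[3, 4, 5]),
    ]
    return MolecularSystem(atoms=atoms, bonds=[], molecules=mols, box=(60, 60, 90))


@pytest.mark.parametrize(
    "axis,leaflet,expected",
    [
        ((0, 0, 1), Leaflet.UPPER, 0.0),
        ((1, 0, 0), Leaflet.UPPER, 90.0),
        ((0, 0, -1), Leaflet.UPPER, 180.0),
        ((0, 0, -1), Leaflet.LOWER, 0.0),  # leaflet normal flips for the lower leaflet
    ],
)
def test_orientation_angle_reference_axes(axis, leaflet, expected):
    traj = Trajectory.from_system(_axis_system(axis, leaflet))
    recs = an.orientation_angles(traj, Species.L5)
    assert len(recs) == 1
    assert recs[0].theta_deg == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("theta,expected", [(0.0, 1.0), (90.0, -0.5), (54.7356, 0.0)])
def test_order_parameter_closed_forms(theta, expected):
    recs = [OrientationRecord(1, 0, theta)] * 10
    res = an.modified_order_parameter(recs)
    assert res.S == pytest.approx(expected, abs=1e-4)


def test_order_parameter_isotropic_is_zero():
    rng = np.random.default_rng(11)
    # isotropic axes: cos(theta) uniform on [-1, 1]
    thetas = np.degrees(np.arccos(rng.uniform(-1, 1, 100_000)))
    res = an.modified_order_parameter(thetas)
    assert abs(res.S) < 0.01
    assert -0.5 <= res.S <= 1.0


def test_order_parameter_empty_rejected():
    with pytest.raises(ValueError):
        an.modified_order_parameter([])


def test_order_parameter_bounded_for_any_angles():
    rng = np.random.default_rng(3)
    for _ in range(50):
        thetas = rng.uniform(0, 180, 100)
        assert -0.5 <= an.modified_order_parameter(thetas).S <= 1.0


# ---------------------------------------------------------------------------
# crossing angles


def test_parallel_tails_all_probability_at_plus_one():
    sys0 = _l5_pair_system([(0, 0, 1), (0, 0, 1)], [(10, 10, 45), (15, 10, 45)])
    h = an.crossing_angle_distribution(Trajectory.from_system(sys0))
    assert len(h.probabilities) == 25
    assert h.probabilities.sum() == pytest.approx(1.0)
    assert h.probabilities[-1] == pytest.approx(1.0)  # bin containing cos=+1


def test_distant_tails_excluded_by_cutoff():
    sys0 = _l5_pair_system([(0, 0, 1), (0, 0, 1)], [(10, 10, 45), (25, 10, 45)])
    h = an.crossing_angle_distribution(Trajectory.from_system(sys0))
    assert h.is_empty


def test_cutoff_uses_minimum_image_in_plane():
    sys0 = _l5_pair_system([(0, 0, 1), (0, 0, 1)], [(2, 10, 45), (58, 10, 45)])
    h = an.crossing_angle_distribution(Trajectory.from_system(sys0))
    assert h.n_pairs == 1  # 4 A apart across the boundary


def test_reflection_symmetry_of_signed_cosine():
    """Reversing one tail of a pair mirrors the histogram (bin i -> 24-i);
    reversing both leaves the signed cosine, hence the histogram, unchanged."""
    rng = np.random.default_rng(17)
    for _ in range(10):
        t1 = rng.normal(size=3)
        t1 /= np.linalg.norm(t1)
        t2 = rng.normal(size=3)
        t2 /= np.linalg.norm(t2)
        mids = [(10, 10, 45), (14, 10, 45)]
        h = an.crossing_angle_distribution(
            Trajectory.from_system(_l5_pair_system([t1, t2], mids))
        )
        h_one = an.crossing_angle_distribution(
            Trajectory.from_system(_l5_pair_system([t1, -t2], mids))
        )
        h_both = an.crossing_angle_distribution(
            Trajectory.from_system(_l5_pair_system([-t1, -t2], mids))
        )
        assert np.allclose(h_one.probabilities, h.probabilities[::-1])
        assert np.allclose(h_both.probabilities, h.probabilities)


def test_isotropic_tails_give_flat_histogram():
    """Randomly oriented packed tails produce a flat cos(theta) distribution."""
    rng = np.random.default_rng(23)
    n = 1000
    tails = rng.normal(size=(n, 3))
    tails /= np.linalg.norm(tails, axis=1, keepdims=True)
    mids = np.column_stack(
        [rng.uniform(0, 60, n), rng.uniform(0, 60, n), np.full(n, 45.0)]
    )
    h = an.crossing_angle_distribution(Trajectory.from_system(_l5_pair_system(tails, mids)))
    assert h.probabilities.sum() == pytest.approx(1.0)
    p = 1.0 / 25
    sigma = np.sqrt(p * (1 - p) / h.n_pairs)
    assert np.all(np.abs(h.probabilities - p) < 4 * sigma + 1e-12)
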