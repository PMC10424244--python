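"""Synthetic bilayer generator: counts, determinism, planted structure."""

import numpy as np
import pytest

import lnptools as lp
from lnptools import analysis as an
from lnptools.errors import FixtureError
from lnptools.geometry import pairwise_min_distance
from lnptools.species import Leaflet, Protonation, Species


def _spec(**kw):
    defaults = dict(
        lattice_nx=10,
        lattice_ny=10,
        composition=lp.CompositionSpec(
            total_lipids_per_leaflet=100, l5_fraction=0.0, chol_fraction=0.0
        ),
        seed=1,
    )
    defaults.update(kw)
    return lp.FixtureSpec(**defaults)


def test_dspc_only_lattice_counts():
    sys0 = lp.generate_bilayer(_spec())
    assert len(sys0.molecules) == 200
    sys0 = lp.assign_leaflets(sys0)
    upper = [m for m in sys0.molecules if m.leaflet is Leaflet.UPPER]
    lower = [m for m in sys0.molecules if m.leaflet is Leaflet.LOWER]
    assert len(upper) == len(lower) == 100
    assert all(m.species is Species.DSPC for m in sys0.molecules)


def test_same_seed_bit_identical():
    a = lp.generate_bilayer(_spec())
    b = lp.generate_bilayer(_spec())
    assert np.array_equal(a.positions, b.positions)
    c = lp.generate_bilayer(_spec(seed=2))
    assert not np.array_equal(a.positions, c.positions)


def test_infinite_concentration_gives_exact_tilt():
    spec = _spec(tilt={Species.DSPC: lp.TiltModel(mean_deg=15.0, kappa=np.inf)})
    sys0 = lp.assign_leaflets(lp.generate_bilayer(spec))
    traj = lp.generate_trajectory(sys0, 1, 0.0, seed=0)
    recs = an.orientation_angles(traj, Species.DSPC)
    thetas = np.array([r.theta_deg for r in recs])
    assert np.allclose(thetas, 15.0, atol=1e-6)


def test_min_separation_respected():
    spec = _spec(
        composition=lp.CompositionSpec(
            total_lipids_per_leaflet=100, l5_fraction=0.3, chol_fraction=0.4
        )
    )
    sys0 = lp.generate_bilayer(spec)
    assert pairwise_min_distance(sys0.positions, sys0.box) >= 1.5


def test_overfull_lattice_rejected():
    with pytest.raises(FixtureError):
        lp.generate_bilayer(
            _spec(
                composition=lp.CompositionSpec(
                    total_lipids_per_leaflet=101, l5_fraction=0.0, chol_fraction=0.0
                )
            )
        )


def test_fixture_passes_leaflet_assignment_and_validation():
    spec = _spec(
        composition=lp.CompositionSpec(
            total_lipids_per_leaflet=90, l5_fraction=0.2, chol_fraction=0.4
        ),
        water_mode="slab",
    )
    sys0 = lp.generate_bilayer(spec)
    sys0.validate()
    labeled = lp.assign_leaflets(sys0)
    lipid = [m for m in labeled.molecules if m.species is not Species.WATER]
    assert all(m.leaflet is not Leaflet.UNASSIGNED for m in lipid)


# ---------------------------------------------------------------------------
# trajectories


def test_zero_jitter_frames_identical(small_bilayer):
    traj = lp.generate_trajectory(small_bilayer, 3, 0.0, seed=1)
    for f in traj.frames:
        assert np.array_equal(f, small_bilayer.positions)


def test_jitter_variance_matches(small_bilayer):
    sigma = 0.7
    traj = lp.generate_trajectory(small_bilayer, 10, sigma, seed=2)
    disp = np.concatenate([f - small_bilayer.positions for f in traj.frames]).ravel()
    assert disp.size >= 10_000
    assert np.var(disp) == pytest.approx(sigma**2, rel=0.05)


def test_trajectory_seed_determinism(small_bilayer):
    a = lp.generate_trajectory(small_bilayer, 2, 0.3, seed=5)
    b = lp.generate_trajectory(small_bilayer, 2, 0.3, seed=5)
    assert np.array_equal(a.frames[1], b.frames[1])


# ---------------------------------------------------------------------------
# planted structure


@pytest.fixture(scope="module")
def l5_bilayer():
    # 65 aminolipids per leaflet so that 60 neutral ones exist for planting
    spec = _spec(
        lattice_nx=12,
        lattice_ny=12,
        composition=lp.CompositionSpec(
            total_lipids_per_leaflet=144, l5_fraction=0.45, chol_fraction=0.30
        ),
        seed=4,
    )
    return lp.assign_leaflets(lp.generate_bilayer(spec))


def test_planted_aggregate_is_one_cluster(l5_bilayer):
    planted = lp.plant_core_aggregate(l5_bilayer, 60, radius=4.0, seed=9)
    sel = an.atom_selector(species=Species.L5, protonation=Protonation.NEUTRAL, name="N")(planted)
    heads = planted.positions[sel]
    # restrict to the planted blob: all 60 nitrogens within radius of the centre
    out = an.cluster_aggregates(heads, planted.box, eps=5.0, min_points=50)
    assert out.n_clusters >= 1
    biggest = max(np.bincount(out.labels[out.labels >= 0]))
    assert biggest >= 60


def test_plant_zero_is_identity(l5_bilayer):
    out = lp.plant_core_aggregate(l5_bilayer, 0, radius=4.0, seed=9)
    assert np.array_equal(out.positions, l5_bilayer.positions)


def test_plant_more_than_available_rejected(l5_bilayer):
    with pytest.raises(FixtureError):
        lp.plant_core_aggregate(l5_bilayer, 10_000, radius=4.0, seed=9)


def test_planted_isotropic_orientations_have_zero_order(l5_bilayer):
    planted = lp.plant_core_aggregate(l5_bilayer, 60, radius=6.0, seed=10)
    core = [
        m for m in planted.molecules
        if m.species is Species.L5 and m.leaflet is Leaflet.CORE
    ]
    assert len(core) == 60
    traj = lp.generate_trajectory(planted, 1, 0.0, seed=0)
    # core molecules are measured against +z by convention
    recs = [
        r
        for r in an.orientation_angles(traj, Species.L5, protonation=Protonation.NEUTRAL)
        if planted.molecule(r.molecule_id).leaflet is Leaflet.CORE
    ]
    res = an.modified_order_parameter(recs)
    assert abs(res.S) < 0.2  # isotropic at n=60: 0 +/- a few sigma


def test_planted_peak_recovered(l5_bilayer):
    planted = lp.plant_density_population(
        l5_bilayer, [lp.PlantedPeak(z=25.0, sigma=3.0, count=10_000)], seed=11
    )
    traj = lp.generate_trajectory(planted, 1, 0.0, seed=0)
    sel = an.atom_selector(species=Species.L5, protonation=Protonation.PROTONATED, name="N")
    prof = an.scaled_mass_density(traj, sel)
    assert abs(prof.peak_z - 25.0) <= prof.slice_width


def test_two_symmetric_peaks_both_unit(l5_bilayer):
    base = _spec()
    sys0 = lp.generate_bilayer(base)
    planted = lp.plant_density_population(
        sys0,
        [
            lp.PlantedPeak(z=25.0, sigma=0.01, count=500),
            lp.PlantedPeak(z=-25.0, sigma=0.01, count=500),
        ],
        seed=12,
    )
    traj = lp.generate_trajectory(planted, 1, 0.0, seed=0)
    sel = an.atom_selector(species=Species.L5, name="N")
    prof = an.scaled_mass_density(traj, sel)
    unit_bins = np.nonzero(prof.scaled_counts == 1.0)[0]
    assert len(unit_bins) == 2


def test_plant_zero_count_adds_nothing(l5_bilayer):
    out = lp.plant_density_population(
        l5_bilayer, [lp.PlantedPeak(z=10.0, sigma=1.0, count=0)], seed=13
    )
    assert out.n_atoms == l5_bilayer.n_atoms
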