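"""Density profiles, projections, and the analysis window."""

import numpy as np
import pytest

import lnptools as lp
from lnptools import analysis as an
from lnptools.species import Protonation, Species
from lnptools.system import AtomRecord, MolecularSystem, Molecule, Trajectory


def _slab_system(marker_zs, box=(50.0, 50.0, 90.0)):
    """Two DSPC anchors defining a midplane at z=45 plus nitrogen markers."""
    atoms = [
        AtomRecord(1, "P", "P", 1, "DSPC", (10.0, 10.0, 65.0)),
        AtomRecord(2, "P", "P", 2, "DSPC", (20.0, 20.0, 25.0)),
    ]
    mols = [
        Molecule(1, Species.DSPC, atom_ids=[1]),
        Molecule(2, Species.DSPC, atom_ids=[2]),
    ]
    aid = 3
    for z in marker_zs:
        atoms.append(AtomRecord(aid, "N", "N", aid, "L5P", (3.0, 4.0, 45.0 + z)))
        mols.append(Molecule(aid, Species.L5, Protonation.PROTONATED, atom_ids=[aid]))
        aid += 1
    return MolecularSystem(atoms=atoms, bonds=[], molecules=mols, box=box)


N_SEL = an.atom_selector(species=Species.L5, name="N")


def test_single_z_population_gives_single_unit_bin():
    traj = Trajectory.from_system(_slab_system([12.0, 12.0, 12.0]))
    prof = an.scaled_mass_density(traj, N_SEL)
    assert prof.scaled_counts.max() == 1.0
    nonzero = np.nonzero(prof.raw_counts)[0]
    assert len(nonzero) == 1
    center = prof.bin_centers[nonzero[0]]
    assert abs(center - 12.0) <= prof.slice_width / 2 + 1e-9


def test_symmetric_populations_both_scaled_to_one():
    traj = Trajectory.from_system(_slab_system([25.0, 25.0, -25.0, -25.0]))
    prof = an.scaled_mass_density(traj, N_SEL)
    hot = prof.scaled_counts[prof.raw_counts > 0]
    assert np.allclose(hot, 1.0)
    assert len(hot) == 2


def test_empty_selection_gives_sentinel():
    traj = Trajectory.from_system(_slab_system([]))
    prof = an.scaled_mass_density(traj, N_SEL)
    assert prof.is_empty
    assert prof.raw_counts.sum() == 0


def test_gaussian_peak_recovered_within_one_bin():
    rng = np.random.default_rng(21)
    zs = rng.normal(25.0, 3.0, 10_000)
    traj = Trajectory.from_system(_slab_system(zs))
    prof = an.scaled_mass_density(traj, N_SEL)
    assert abs(prof.peak_z - 25.0) <= prof.slice_width


def test_profile_invariant_under_inplane_translation():
    sys0 = _slab_system([25.0, 12.0, -3.0])
    prof0 = an.scaled_mass_density(Trajectory.from_system(sys0), N_SEL)
    moved = sys0.copy()
    moved.positions[:, :2] += [13.0, -7.0]
    prof1 = an.scaled_mass_density(Trajectory.from_system(moved), N_SEL)
    assert np.allclose(prof0.scaled_counts, prof1.scaled_counts)


# ---------------------------------------------------------------------------
# projections


def test_xz_projection_localizes_single_atom():
    sys0 = _slab_system([5.0])
    sys0.positions[2] = [3.0, 4.0, 50.0]  # marker at x=3, z=midplane+5
    pm = an.project_coordinates(Trajectory.from_system(sys0), N_SEL, "xz")
    i, j = np.unravel_index(np.argmax(pm.histogram), pm.histogram.shape)
    assert pm.x_edges[i] <= 3.0 <= pm.x_edges[i + 1]
    assert pm.y_edges[j] <= 5.0 <= pm.y_edges[j + 1]
    assert (pm.histogram > 0).sum() == 1


def test_projection_conserves_mass():
    sys0 = _slab_system([5.0, 7.0, -2.0])
    traj = lp.generate_trajectory(sys0, n_frames=3, jitter_sigma=0.1, seed=1)
    pm = an.project_coordinates(traj, N_SEL, "xz")
    from lnptools.chem import mass_of

    expect = 3 * 3 * mass_of("N")  # three markers, three frames
    assert pm.histogram.sum() == pytest.approx(expect)
    assert pm.total_mass == pytest.approx(expect)


def test_unknown_plane_rejected():
    traj = Trajectory.from_system(_slab_system([1.0]))
    with pytest.raises(ValueError):
        an.project_coordinates(traj, N_SEL, "yz")


def test_planted_midplane_blob_found_in_xz_map():
    spec = lp.FixtureSpec(
        lattice_nx=8, lattice_ny=8,
        composition=lp.CompositionSpec(
            total_lipids_per_leaflet=64, l5_fraction=0.4, chol_fraction=0.4
        ),
        seed=3,
    )
    sys0 = lp.assign_leaflets(lp.generate_bilayer(spec))
    sys0 = lp.plant_core_aggregate(sys0, 20, radius=3.0, seed=4)
    sel = an.atom_selector(species=Species.L5, protonation=Protonation.NEUTRAL, name="N")
    pm = an.project_coordinates(Trajectory.from_system(sys0), sel, "xz")
    i, j = np.unravel_index(np.argmax(pm.histogram), pm.histogram.shape)
    x_peak = 0.5 * (pm.x_edges[i] + pm.x_edges[i + 1])
    z_peak = 0.5 * (pm.y_edges[j] + pm.y_edges[j + 1])
    assert abs(x_peak - sys0.box[0] / 2) <= 3.0 + 1.0
    assert abs(z_peak) <= 3.0 + 1.0


# ---------------------------------------------------------------------------
# analysis window and replicate averaging


def test_last_third_window():
    sys0 = _slab_system([1.0])
    traj = lp.generate_trajectory(sys0, n_frames=9, jitter_sigma=0.1, seed=5)
    w = an.analysis_window(traj)
    assert w.n_frames == 3
    assert np.allclose(w.frames[0], traj.frames[6])


def test_full_window_is_identity():
    sys0 = _slab_system([1.0])
    traj = lp.generate_trajectory(sys0, n_frames=4, jitter_sigma=0.1, seed=5)
    w = an.analysis_window(traj, fraction=1.0)
    assert w.n_frames == 4


def test_replicate_mean_of_identical_is_exact():
    mean, std = an.replicate_mean([0.42, 0.42, 0.42])
    assert mean == pytest.approx(0.42)
    assert std == 0.0
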