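"""Composition arithmetic, protonation splits, replacement selection, study plan."""

import numpy as np
import pytest

import lnptools as lp
from lnptools.composition import assign_protonation_per_leaflet
from lnptools.errors import CompositionError, SelectionError
from lnptools.species import Leaflet, Protonation, Species
from lnptools.study import StudyDesign, derive_seed, plan_study


def test_forty_forty_split_of_250():
    spec = lp.CompositionSpec(total_lipids_per_leaflet=250, l5_fraction=0.40, chol_fraction=0.40)
    counts = lp.plan_composition(spec)
    for leaflet in (Leaflet.UPPER, Leaflet.LOWER):
        c = counts[leaflet]
        assert (c.n_chol, c.n_l5, c.n_dspc) == (100, 100, 50)


def test_zero_l5_leaves_input_composition():
    spec = lp.CompositionSpec(total_lipids_per_leaflet=100, l5_fraction=0.0, chol_fraction=0.40)
    c = lp.plan_composition(spec)[Leaflet.UPPER]
    assert (c.n_dspc, c.n_chol, c.n_l5) == (60, 40, 0)


def test_infeasible_composition_raises():
    # fractions summing past one are rejected at construction
    with pytest.raises(CompositionError):
        lp.CompositionSpec(total_lipids_per_leaflet=10, l5_fraction=0.70, chol_fraction=0.40)
    # feasible fractions whose rounded counts exceed the leaflet are caught in planning
    spec = lp.CompositionSpec(total_lipids_per_leaflet=5, l5_fraction=0.5, chol_fraction=0.5)
    with pytest.raises(CompositionError):
        lp.plan_composition(spec)


def test_fraction_bounds_validated():
    with pytest.raises(CompositionError):
        lp.CompositionSpec(total_lipids_per_leaflet=10, l5_fraction=1.2)


@pytest.mark.parametrize(
    "n,fraction,expected_prot",
    [(200, 0.5, 100), (0, 0.5, 0), (5, 0.5, 3), (7, 0.25, 2)],
)
def test_protonation_counts_round_half_up(n, fraction, expected_prot):
    labels = lp.assign_protonation(n, fraction, seed=1)
    assert len(labels) == n
    assert labels.count(Protonation.PROTONATED) == expected_prot


def test_protonation_randomized_but_seeded():
    a = lp.assign_protonation(20, 0.5, seed=9)
    b = lp.assign_protonation(20, 0.5, seed=9)
    c = lp.assign_protonation(20, 0.5, seed=10)
    assert a == b
    assert a != c


def test_per_leaflet_balance_within_one():
    for n in (10, 11, 25):
        out = assign_protonation_per_leaflet(
            {Leaflet.UPPER: n, Leaflet.LOWER: n}, fraction=0.5, seed=2
        )
        up = out[Leaflet.UPPER].count(Protonation.PROTONATED)
        lo = out[Leaflet.LOWER].count(Protonation.PROTONATED)
        assert abs(up - lo) <= 1
        assert up + lo == round(0.5 * 2 * n + 1e-9)


def test_selection_deterministic_and_leaflet_restricted(small_bilayer):
    counts = {Leaflet.UPPER: 5, Leaflet.LOWER: 5}
    a = lp.select_replacements(small_bilayer, counts, seed=4)
    b = lp.select_replacements(small_bilayer, counts, seed=4)
    c = lp.select_replacements(small_bilayer, counts, seed=5)
    assert a == b and set(a) != set(c)
    assert len(a) == 10
    for mid in a:
        assert small_bilayer.molecule(mid).species is Species.DSPC


def test_selection_error_when_insufficient(small_bilayer):
    with pytest.raises(SelectionError):
        lp.select_replacements(small_bilayer, {Leaflet.UPPER: 10**4}, seed=0)


def test_selection_frequencies_uniform(small_bilayer):
    """Repeated 1-of-pool draws hit each candidate uniformly (multinomial check)."""
    pool = [
        m.molecule_id
        for m in small_bilayer.molecules
        if m.species is Species.DSPC and m.leaflet is Leaflet.UPPER
    ][:10]
    n_draws = 10_000
    hits = {mid: 0 for mid in pool}
    sub = small_bilayer
    for seed in range(n_draws):
        picks = lp.select_replacements(sub, {Leaflet.UPPER: 1}, seed=seed)
        if picks[0] in hits:
            hits[picks[0]] += 1
    total = sum(hits.values())
    n_pool = sum(
        1
        for m in small_bilayer.molecules
        if m.species is Species.DSPC and m.leaflet is Leaflet.UPPER
    )
    p = 1.0 / n_pool
    sigma = np.sqrt(n_draws * p * (1 - p))
    for mid in pool:
        assert abs(hits[mid] - n_draws * p) < 4 * sigma
    assert total <= n_draws


# ---------------------------------------------------------------------------
# study design


def test_default_design_reproduces_sampling_arithmetic():
    plan = plan_study(StudyDesign())
    assert plan.per_composition_sampling_us == pytest.approx(9.0)
    assert plan.total_sampling_us == pytest.approx(45.0)
    assert len(plan.jobs) == 15


@pytest.mark.parametrize(
    "compositions,reps,prod,total",
    [((0.3,), 1, 3.0, 3.0), ((0.2, 0.4), 2, 0.2, 0.8)],
)
def test_design_arithmetic(compositions, reps, prod, total):
    plan = plan_study(
        StudyDesign(compositions=compositions, replicates_per_composition=reps,
                    production_length_us=prod)
    )
    assert plan.total_sampling_us == pytest.approx(total)


def test_invalid_design_rejected():
    with pytest.raises(ValueError):
        StudyDesign(compositions=(0.4, 0.2))
    with pytest.raises(ValueError):
        StudyDesign(replicates_per_composition=0)


def test_derived_seeds_stable_and_distinct():
    assert derive_seed(1, "a") == derive_seed(1, "a")
    assert derive_seed(1, "a") != derive_seed(1, "b")
    assert 0 <= derive_seed(123456, "stage") < 2**31
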