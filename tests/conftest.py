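import warnings

import pytest

warnings.filterwarnings("ignore", module="MDAnalysis")

import lnptools as lp


@pytest.fixture(scope="session")
def small_bilayer():
    """36-lipid-per-leaflet DSPC/cholesterol bilayer with a water slab."""
    spec = lp.FixtureSpec(
        lattice_nx=6,
        lattice_ny=6,
        composition=lp.CompositionSpec(
            total_lipids_per_leaflet=36, l5_fraction=0.0, chol_fraction=0.40
        ),
        water_mode="slab",
        seed=11,
    )
    return lp.assign_leaflets(lp.generate_bilayer(spec))


@pytest.fixture(scope="session")
def l5_template():
    return lp.default_l5_template()
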