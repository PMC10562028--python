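import numpy as np
import pytest

from muv.dicom_io import ArcBeam, ControlPoint, VMATPlan
from muv.fixtures import PhantomRecipe, Region, make_ct, water_cube_recipe
from muv.phantom import build_phantom


@pytest.fixture(scope="session")
def water_ct():
    return make_ct(water_cube_recipe(side_mm=100.0, spacing_mm=5.0), seed=0)


@pytest.fixture(scope="session")
def slab_ct():
    """water / lung(-750) / water slabs along y, aligned to the 2 mm grid."""
    recipe = PhantomRecipe(
        extent_mm=(40.0, 60.0, 40.0), spacing_mm=(2.0, 2.0, 2.0),
        background_hu=0.0,
        regions=(Region(shape="slab", axis="y", hu=-750.0, lo=-10.0, hi=10.0),),
    )
    return make_ct(recipe, seed=0)


def static_beam(halfsize_mm=50.0, energy="6X", mu=100.0, gantry=0.0):
    jaws = (-halfsize_mm, halfsize_mm, -halfsize_mm, halfsize_mm)
    boundaries = np.array([-100.0, 100.0])
    mlc = np.array([[-halfsize_mm], [halfsize_mm]])
    cps = [ControlPoint(gantry_deg=gantry, jaws=jaws, mlc=mlc, cum_weight=0.0),
           ControlPoint(gantry_deg=gantry, jaws=jaws, mlc=mlc, cum_weight=1.0)]
    return ArcBeam(energy=energy, beam_mu=mu, control_points=cps,
                   leaf_boundaries=boundaries, is_arc=False)


@pytest.fixture(scope="session")
def small_water_phantom(water_ct):
    return build_phantom(water_ct)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
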