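import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muv.dicom_io import ROI, TPSDose
from muv.evaluation import (
    EvalConfig,
    EvalReport,
    PointComparison,
    compare,
    point_dose,
    select_reference_points,
    study_summary,
)
from muv.fixtures import make_ct, sphere_roi, water_cube_recipe
from muv.geometry import Geometry


@pytest.fixture(scope="module")
def ct():
    return make_ct(water_cube_recipe(side_mm=120.0, spacing_mm=2.0), seed=0)


def uniform_dose(geometry, value=2.0):
    return TPSDose(dose=np.full(geometry.shape, value), geometry=geometry)


# -- reference point selection -------------------------------------------------

def test_sphere_selection_five_points(ct):
    ptv = sphere_roi(ct, (0.0, 0.0, 0.0), 20.0)
    pts = select_reference_points(ptv)
    assert pts.points_mm.shape == (5, 3)
    assert pts.offset_axes == ("z", "x")
    # centroid at the symmetry center within half a voxel
    assert np.all(np.abs(pts.points_mm[0]) <= 1.0)
    sup_inf = pts.points_mm[1:3]
    assert np.allclose(np.abs(sup_inf[:, 2] - pts.points_mm[0, 2]), 7.5)
    assert not pts.pulled_inward


def test_flat_ptv_switches_to_lateral(ct):
    # disc: sup-inf extent 6 mm < 2*(7.5+2) -> lateral axes
    geom = ct.geometry
    mask = np.zeros(geom.shape, dtype=bool)
    zc = geom.shape[0] // 2
    xs = geom.axis_centers(0)
    ys = geom.axis_centers(1)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    disc = gx**2 + gy**2 <= 25.0**2
    for dz in (-1, 0, 1):  # 6 mm thick
        mask[zc + dz][disc] = True
    pts = select_reference_points(ROI(name="PTV", mask=mask, geometry=geom))
    assert pts.offset_axes == ("x", "y")


def test_offset_point_pulled_inward(ct):
    # radius barely above the offset: +-7.5 mm z-offsets fall outside and
    # are pulled back along their axis
    ptv = sphere_roi(ct, (0.0, 0.0, 0.0), 6.0)
    config = EvalConfig(offset_mm=7.5, axis_margin_mm=-5.0)  # force z axis
    pts = select_reference_points(ptv, config)
    assert pts.pulled_inward  # some points were adjusted
    from muv.evaluation import _inside_mask

    assert np.all(_inside_mask(ptv, pts.points_mm))


def test_tiny_ptv_rejected(ct):
    ptv = sphere_roi(ct, (0.0, 0.0, 0.0), 2.0)
    with pytest.raises(ValueError, match="too small|collapse"):
        select_reference_points(ptv)


def test_empty_ptv_rejected(ct):
    roi = ROI(name="PTV", mask=np.zeros(ct.geometry.shape, dtype=bool),
              geometry=ct.geometry)
    with pytest.raises(ValueError, match="empty"):
        select_reference_points(roi)


# -- point dose ----------------------------------------------------------------

def test_point_dose_voxel_center():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(4, 4, 4))
    dose = np.arange(64, dtype=float).reshape(4, 4, 4)
    assert point_dose((dose, geom), [2.0, 4.0, 6.0]) == dose[3, 2, 1]


def test_point_dose_midpoint_mean():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(2, 2, 2))
    dose = np.zeros((2, 2, 2))
    dose[0, 0, 0], dose[0, 0, 1] = 1.0, 3.0
    assert point_dose((dose, geom), [1.0, 0.0, 0.0]) == pytest.approx(2.0)


def test_point_dose_constant_field():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(3, 3, 3))
    d = uniform_dose(geom, 1.7)
    rng = np.random.default_rng(0)
    for _ in range(10):
        p = rng.uniform(0.0, 4.0, 3)
        assert point_dose(d, p) == pytest.approx(1.7, rel=1e-12)


def test_point_dose_outside_rejected():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(2, 2, 2))
    with pytest.raises(ValueError, match="outside"):
        point_dose(uniform_dose(geom), [100.0, 0.0, 0.0])


# -- compare --------------------------------------------------------------------

def grid_points():
    return np.array([[2.0, 2.0, 2.0], [4.0, 2.0, 2.0], [2.0, 4.0, 2.0],
                     [4.0, 4.0, 2.0], [2.0, 2.0, 4.0]])


def test_boundary_five_percent_not_flagged():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(4, 4, 4))
    tps = uniform_dose(geom, 2.00)
    sec = uniform_dose(geom, 2.10)  # exactly +5.0%
    rep = compare(tps, sec, grid_points())
    assert all(p.percent_diff == pytest.approx(5.0) for p in rep.points)
    assert rep.n_exceeding == 0  # strict inequality at the action limit


def test_derived_summary_arithmetic():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(4, 4, 4))
    tps = uniform_dose(geom, 1.0)
    sec = np.array([1.03, 0.97, 1.08, 0.92, 1.00])
    rep = compare(tps, sec, grid_points())
    s = rep.summary()
    assert s["mean"] == pytest.approx(0.0, abs=1e-9)
    assert s["mean_abs"] == pytest.approx(4.4)
    assert s["fraction_exceeding"] == pytest.approx(0.4)


def test_identical_grids_zero_diffs():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(4, 4, 4))
    tps = uniform_dose(geom, 2.0)
    rep = compare(tps, tps, grid_points())
    assert np.allclose(rep.diffs, 0.0)
    assert rep.n_exceeding == 0


def test_zero_tps_point_excluded():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(4, 4, 4))
    dose = np.full(geom.shape, 2.0)
    dose[1, 1, 1] = 0.0
    for off in ((0, 1), (1, 0), (1, 2), (2, 1)):
        pass
    tps = TPSDose(dose=np.zeros(geom.shape), geometry=geom)
    sec = uniform_dose(geom, 1.0)
    with pytest.warns(UserWarning, match="zero"):
        rep = compare(tps, sec, grid_points())
    assert rep.n_valid == 0
    assert all(not p.valid for p in rep.points)


def test_sign_flip_antisymmetry():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(4, 4, 4))
    tps = uniform_dose(geom, 2.0)
    sec = uniform_dose(geom, 2.2)
    fwd = compare(tps, sec, grid_points()).diffs
    # sign of (D_sec - D_tps) flips when the roles swap
    rev = compare(sec, tps, grid_points()).diffs
    assert np.all(np.sign(fwd) == -np.sign(rev))


@given(st.permutations(range(5)))
@settings(max_examples=20, deadline=None)
def test_summary_permutation_invariant(perm):
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(4, 4, 4))
    tps = uniform_dose(geom, 1.0)
    sec = np.array([1.03, 0.97, 1.08, 0.92, 1.01])
    pts = grid_points()
    base = compare(tps, sec, pts).summary()
    shuffled = compare(tps, sec[list(perm)], pts[list(perm)]).summary()
    for k in ("mean", "mean_abs", "std", "q1", "median", "q3"):
        assert shuffled[k] == pytest.approx(base[k])


def test_mean_abs_geq_abs_mean():
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(4, 4, 4))
    tps = uniform_dose(geom, 1.0)
    sec = np.array([1.05, 0.93, 1.02, 0.99, 1.10])
    s = compare(tps, sec, grid_points()).summary()
    assert s["mean_abs"] >= abs(s["mean"]) - 1e-12


# -- study summary ---------------------------------------------------------------

def _report(n_exceed, n=5, site="lung", method="mc"):
    pts = [PointComparison((0, 0, 0), 1.0, 1.0, 8.0 if k < n_exceed else 1.0,
                           k < n_exceed) for k in range(n)]
    return EvalReport(points=pts, action_limit_percent=5.0,
                      meta={"site": site, "method": method})


def test_pooled_count_37_arcs():
    reports = [_report(0) for _ in range(37)]
    s = study_summary(reports)
    assert s["n_points"] == 185
    assert s["n_arcs"] == 37


def test_single_arc_fraction():
    s = study_summary([_report(1)])
    assert s["fraction_exceeding"] == pytest.approx(0.2)


def test_pooled_fraction_is_count_weighted():
    reports = [_report(1, n=5), _report(3, n=5), _report(0, n=5)]
    s = study_summary(reports)
    fr = [r.fraction_exceeding for r in reports]
    assert s["fraction_exceeding"] == pytest.approx(np.mean(fr))
    assert s["n_exceeding"] == 4


def test_by_site_aggregation():
    reports = [_report(1, site="lung"), _report(0, site="brain")]
    s = study_summary(reports)
    assert s["by_site"]["lung"]["n_exceeding"] == 1
    assert s["by_site"]["brain"]["n_exceeding"] == 0


def test_config_validation():
    with pytest.raises(ValueError):
        EvalConfig(action_limit_percent=-1.0)
    with pytest.raises(ValueError):
        EvalConfig(offset_mm=3.0)
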