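import numpy as np
import pytest

from muv import _dicom
from muv.dicom_io import (
    read_ct_series,
    read_rtdose,
    read_rtplan,
    read_structures,
    strip_identifiers,
    write_rtdose,
    read_case,
    write_case,
)
from muv.fixtures import (
    PlanRecipe,
    make_plan,
    make_ct,
    water_cube_recipe,
    write_ct_series,
    write_rtplan,
    write_rtstruct,
)
from muv.geometry import Geometry


# -- CT series ---------------------------------------------------------------

def test_ct_rescale_identity(tmp_path, water_ct):
    # stored value 24 with intercept -1024 decodes to HU -1000
    ct = water_ct
    files = write_ct_series(ct, tmp_path / "ct", seed=1)
    ds = _dicom.read_file(files[0])
    stored = np.frombuffer(ds.PixelData, dtype="<i2")
    assert stored[0] == 1024  # HU 0 stored as 1024
    loaded = read_ct_series(tmp_path / "ct")
    assert np.array_equal(loaded.hu, ct.hu)


def test_ct_round_trip_geometry(tmp_path, slab_ct):
    write_ct_series(slab_ct, tmp_path / "ct", seed=2)
    loaded = read_ct_series(tmp_path / "ct")
    assert np.array_equal(loaded.hu, slab_ct.hu)
    assert loaded.geometry.approx_equal(slab_ct.geometry)


def test_ct_missing_slice_detected(tmp_path, water_ct):
    files = write_ct_series(water_ct, tmp_path / "ct", seed=3)
    files[7].unlink()  # create a spacing gap
    with pytest.raises(ValueError, match="non-uniform slice spacing"):
        read_ct_series(tmp_path / "ct")


def test_ct_mixed_series_rejected(tmp_path, water_ct):
    write_ct_series(water_ct, tmp_path / "ct", seed=4)
    other = make_ct(water_cube_recipe(side_mm=100.0, spacing_mm=5.0), seed=9)
    # second series into the same directory with different UIDs
    sub = write_ct_series(other, tmp_path / "other", seed=99)
    (tmp_path / "ct" / "intruder.dcm").write_bytes(sub[0].read_bytes())
    with pytest.raises(ValueError, match="mixed CT series"):
        read_ct_series(tmp_path / "ct")


# -- RT plan -----------------------------------------------------------------

def test_rtplan_98_control_points(tmp_path):
    plan = make_plan(PlanRecipe(n_arcs=1, control_points=98, energy="6FFF"))
    path = write_rtplan(plan, tmp_path / "plan.dcm")
    loaded = read_rtplan(path)
    cps = loaded.beams[0].control_points
    assert len(cps) == 98
    assert cps[0].cum_weight == 0.0
    assert cps[97].cum_weight == 1.0
    assert loaded.beams[0].energy == "6FFF"


def test_rtplan_two_arcs_independent_mu(tmp_path):
    plan = make_plan(PlanRecipe(n_arcs=2, control_points=10, beam_mu=150.0))
    plan.beams[1].beam_mu = 250.0
    path = write_rtplan(plan, tmp_path / "plan.dcm")
    loaded = read_rtplan(path)
    assert len(loaded.beams) == 2
    assert loaded.beams[0].beam_mu == 150.0
    assert loaded.beams[1].beam_mu == 250.0


def test_rtplan_crossed_leaves_rejected(tmp_path):
    plan = make_plan(PlanRecipe(n_arcs=1, control_points=10))
    path = write_rtplan(plan, tmp_path / "plan.dcm")
    ds = _dicom.read_file(path)
    cp5 = ds.BeamSequence[0].ControlPointSequence[5]
    for dev in cp5.BeamLimitingDevicePositionSequence:
        if dev.RTBeamLimitingDeviceType == "MLCX":
            pos = list(dev.LeafJawPositions)
            n = len(pos) // 2
            pos[3], pos[n + 3] = 30.0, -30.0  # cross pair 3
            dev.LeafJawPositions = pos
    _dicom.write_file(path, ds)
    with pytest.raises(ValueError) as exc:
        read_rtplan(path)
    msg = str(exc.value)
    assert "CP 5" in msg and "3" in msg


def test_rtplan_decreasing_weights_rejected(tmp_path):
    plan = make_plan(PlanRecipe(n_arcs=1, control_points=5))
    path = write_rtplan(plan, tmp_path / "plan.dcm")
    ds = _dicom.read_file(path)
    ds.BeamSequence[0].ControlPointSequence[3].CumulativeMetersetWeight = 0.1
    _dicom.write_file(path, ds)
    with pytest.raises(ValueError, match="decreases"):
        read_rtplan(path)


# -- structures --------------------------------------------------------------

def test_sphere_mask_volume(tmp_path):
    ct = make_ct(water_cube_recipe(side_mm=100.0, spacing_mm=2.0), seed=0)
    path = write_rtstruct(tmp_path / "ss.dcm", ct, [("PTV", (0.0, 0.0, 0.0), 20.0)])
    ss = read_structures(path, ct)
    vol = ss["PTV"].mask.sum() * 2.0**3
    analytic = 4.0 / 3.0 * np.pi * 20.0**3
    assert abs(vol - analytic) / analytic < 0.05


def test_empty_roi_warns(tmp_path, water_ct):
    path = write_rtstruct(tmp_path / "ss.dcm", water_ct, [("GTV", (0, 0, 500.0), 5.0)])
    with pytest.warns(UserWarning, match="no contours|empty"):
        ss = read_structures(path, water_ct)
    assert not ss["GTV"].mask.any()


# -- RT dose -----------------------------------------------------------------

def test_rtdose_round_trip_quantization(tmp_path):
    geom = Geometry(origin=(0, 0, 0), spacing=(2, 2, 2), shape=(5, 6, 7))
    rng = np.random.default_rng(0)
    dose = rng.uniform(0.0, 3.0, geom.shape)
    scaling = write_rtdose(tmp_path / "d.dcm", dose, geom)
    loaded = read_rtdose(tmp_path / "d.dcm")
    assert loaded.geometry.approx_equal(geom)
    assert np.max(np.abs(loaded.dose - dose)) <= scaling


def test_rtdose_round_trip_bitwise(tmp_path):
    geom = Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(3, 3, 3))
    dose = np.full(geom.shape, 2.0)
    write_rtdose(tmp_path / "d.dcm", dose, geom)
    a = read_rtdose(tmp_path / "d.dcm")
    write_rtdose(tmp_path / "d2.dcm", a.dose, geom, scaling=float(a.dose.max() / (2**32 - 1)))
    b = read_rtdose(tmp_path / "d2.dcm")
    assert np.array_equal(a.dose, b.dose)


def test_rtdose_zero_dose(tmp_path):
    geom = Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(2, 2, 2))
    write_rtdose(tmp_path / "z.dcm", np.zeros(geom.shape), geom)
    loaded = read_rtdose(tmp_path / "z.dcm")
    assert not loaded.dose.any()


def test_rtdose_range_error(tmp_path):
    geom = Geometry(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(2, 2, 2))
    with pytest.raises(ValueError, match="representable"):
        write_rtdose(tmp_path / "d.dcm", np.full(geom.shape, 10.0), geom, scaling=1e-12)


def test_dose_grid_finer_than_ct(tmp_path, water_ct):
    # 1.25 mm dose grid loads independently of the 5 mm CT geometry
    geom = Geometry(origin=(0, 0, 0), spacing=(1.25, 1.25, 1.25), shape=(4, 4, 4))
    write_rtdose(tmp_path / "d.dcm", np.ones(geom.shape), geom)
    loaded = read_rtdose(tmp_path / "d.dcm")
    assert loaded.geometry.spacing == (1.25, 1.25, 1.25)
    assert water_ct.geometry.spacing == (5.0, 5.0, 5.0)


# -- de-identification -------------------------------------------------------

def test_strip_replaces_name(tmp_path, water_ct):
    files = write_ct_series(water_ct, tmp_path / "ct", seed=5)
    out = strip_identifiers(files[:3], tmp_path / "anon")
    for f in out:
        ds = _dicom.read_file(f)
        assert ds.PatientName == "ANON^ANON"


def test_strip_uid_consistency(tmp_path, water_ct):
    files = write_ct_series(water_ct, tmp_path / "ct", seed=6)
    plan = make_plan(PlanRecipe(n_arcs=1, control_points=5))
    pf = write_rtplan(plan, tmp_path / "ct" / "plan.dcm", seed=6)
    out = strip_identifiers(files[:2] + [pf], tmp_path / "anon")
    uids = {f.name: _dicom.read_file(f).StudyInstanceUID for f in out}
    assert len(set(uids.values())) == 1  # same study UID remapped consistently
    original = _dicom.read_file(files[0]).StudyInstanceUID
    assert set(uids.values()) != {original}


def test_strip_idempotent(tmp_path, water_ct):
    files = write_ct_series(water_ct, tmp_path / "ct", seed=7)
    once = strip_identifiers(files[:2], tmp_path / "anon1")
    twice = strip_identifiers(once, tmp_path / "anon2")
    for a, b in zip(once, twice):
        assert a.read_bytes() == b.read_bytes()


def test_uid_remap_bijection(tmp_path, water_ct):
    files = write_ct_series(water_ct, tmp_path / "ct", seed=8)
    out = strip_identifiers(files, tmp_path / "anon")
    orig_sops = [_dicom.read_file(f).SOPInstanceUID for f in files]
    new_sops = [_dicom.read_file(f).SOPInstanceUID for f in out]
    assert len(set(orig_sops)) == len(set(new_sops)) == len(files)


# -- case container ----------------------------------------------------------

def test_case_container_round_trip(tmp_path, slab_ct):
    plan = make_plan(PlanRecipe(n_arcs=2, control_points=12))
    write_case(tmp_path / "case.h5", ct=slab_ct, plan=plan)
    data = read_case(tmp_path / "case.h5")
    assert np.array_equal(data["ct"].hu, slab_ct.hu)
    loaded = data["plan"]
    assert len(loaded.beams) == 2
    cp = loaded.beams[0].control_points[3]
    orig = plan.beams[0].control_points[3]
    assert cp.gantry_deg == orig.gantry_deg
    assert np.array_equal(cp.mlc, orig.mlc)
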