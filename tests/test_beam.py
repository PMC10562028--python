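import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muv.beam import (
    Aperture,
    BeamSource,
    PhaseSpaceRecord,
    PhaseSpaceSet,
    arc_segments,
    collimate,
    collimate_batch,
    concatenate_phase_space,
    differential_mu,
    read_phase_space,
    sample_source,
    write_phase_space,
)
from muv.dicom_io import VMATPlan
from muv.fixtures import PlanRecipe, make_phase_space, make_plan
from tests.conftest import static_beam


# -- phase space -------------------------------------------------------------

def test_concat_large_declared_counts_sparse():
    files = [make_phase_space(50_000_000, sparse=True, energy="6X") for _ in range(5)]
    merged = concatenate_phase_space(files)
    assert merged.count == 250_000_000
    assert merged.sparse


def test_concat_single_identity():
    ps = make_phase_space(100, seed=3)
    out = concatenate_phase_space([ps])
    assert out.count == 100
    assert np.array_equal(out.records, ps.records)


def test_concat_order_preserved():
    a = make_phase_space(3, seed=1)
    b = make_phase_space(4, seed=2)
    merged = concatenate_phase_space([a, b])
    assert merged.count == 7
    assert np.array_equal(merged.records[:3], a.records)
    assert np.array_equal(merged.records[3:], b.records)


def test_concat_associative():
    sets = [make_phase_space(n, seed=n) for n in (2, 3, 4)]
    left = concatenate_phase_space([concatenate_phase_space(sets[:2]), sets[2]])
    right = concatenate_phase_space([sets[0], concatenate_phase_space(sets[1:])])
    assert left.count == right.count
    assert np.array_equal(left.records, right.records)


def test_concat_mismatch_rejected():
    a = make_phase_space(3, seed=1, energy="6X")
    b = make_phase_space(3, seed=2, energy="10X")
    with pytest.raises(ValueError, match="energy"):
        concatenate_phase_space([a, b])


def test_phsp_file_round_trip(tmp_path):
    ps = make_phase_space(1000, seed=4, energy="10FFF")
    write_phase_space(tmp_path / "a.phsp", ps)
    loaded = read_phase_space(tmp_path / "a.phsp")
    assert loaded.count == 1000
    assert loaded.energy == "10FFF"
    assert np.array_equal(loaded.records, ps.records)


def test_phsp_truncated_count_rejected(tmp_path):
    ps = make_phase_space(10, seed=5)
    write_phase_space(tmp_path / "a.phsp", ps)
    data = (tmp_path / "a.phsp").read_bytes()
    (tmp_path / "bad.phsp").write_bytes(data[:-29])  # drop one record
    with pytest.raises(ValueError, match="declared count"):
        read_phase_space(tmp_path / "bad.phsp")


def test_empty_phase_space_rejected_by_source():
    ps = make_phase_space(0)
    with pytest.raises(ValueError, match="empty"):
        BeamSource(energy="6X", phase_space=ps)


# -- sources -----------------------------------------------------------------

def test_degenerate_spectrum():
    src = BeamSource(energy="6X", spectrum=((1.0, 1.0),))
    rng = np.random.default_rng(0)
    recs = src.sample_batch(rng, 1000)
    assert np.all(recs["E"] == 1.0)


def test_two_line_spectrum_fraction(rng):
    src = BeamSource(energy="6X", spectrum=((2.0, 0.3), (6.0, 0.7)))
    recs = src.sample_batch(rng, 100_000)
    frac = np.mean(recs["E"] == 6.0)
    sigma = math.sqrt(0.7 * 0.3 / 100_000)
    assert abs(frac - 0.7) < 3 * sigma


def test_phase_space_cyclic_draws(rng):
    ps = make_phase_space(10, seed=6)
    src = BeamSource(energy="6X", phase_space=ps)
    recs = src.sample_batch(rng, 25)
    # each of the 10 records drawn 2 or 3 times
    vals, counts = np.unique(recs["x"], return_counts=True)
    assert len(vals) == 10
    assert set(counts) <= {2, 3}
    assert src.passes_completed == 2


def test_sample_source_record_valid(rng):
    src = BeamSource(energy="6X", spectrum=((1.0, 0.5), (2.0, 0.5)))
    rec = sample_source(src, rng)
    assert isinstance(rec, PhaseSpaceRecord)
    assert rec.w > 0 and rec.energy in (1.0, 2.0)


def test_spectrum_validation():
    with pytest.raises(ValueError, match="sum"):
        BeamSource(energy="6X", spectrum=((1.0, 0.5), (2.0, 0.4)))
    with pytest.raises(ValueError, match="ascending"):
        BeamSource(energy="6X", spectrum=((2.0, 0.5), (1.0, 0.5)))


def test_window_subsampling_preserves_fluence(rng):
    """Restricted-window sampling reweights so fluence density is unchanged."""
    src = BeamSource(energy="6X", spectrum=((1.0, 1.0),), window_halfsize_mm=100.0)
    n = 200_000
    full = src.sample_batch(np.random.default_rng(1), n)
    sub = src.sample_batch(np.random.default_rng(2), n, window=(-50, 50, -50, 50))
    # weighted count landing in the sub-window per history matches
    t_full = 1000.0 / full["w"]
    xi = full["x"] + full["u"] * (src.plane_mm / full["w"])
    yi = full["y"] + full["v"] * (src.plane_mm / full["w"])
    inside = (np.abs(xi) <= 50) & (np.abs(yi) <= 50)
    est_full = np.sum(full["wt"][inside]) / n
    est_sub = np.sum(sub["wt"]) / n
    assert est_sub == pytest.approx(est_full, rel=0.02)


# -- collimation -------------------------------------------------------------

def open_10x10():
    return Aperture.open_field(-50.0, 50.0, -50.0, 50.0)


def test_central_ray_transmitted():
    rec = PhaseSpaceRecord(x=0.0, y=0.0, u=0.0, v=0.0, w=1.0, energy=1.0, weight=1.0)
    out = collimate(rec, open_10x10())
    assert out is rec


def test_blocked_ray_absorbed():
    ap = Aperture(jaws=(-50, 50, -50, 50), leaf_boundaries=np.array([-50.0, 50.0]),
                  leaf_open=np.array([[0.0], [0.0]]), transmission=0.0)
    # ray projecting 1 mm outside the closed pair
    rec = PhaseSpaceRecord(x=1.0 * 0.45, y=0.0, u=0.0, v=0.0, w=1.0,
                           energy=1.0, weight=1.0)
    assert collimate(rec, ap) is None


def test_transmission_multiplies_weight():
    ap = Aperture(jaws=(-50, 50, -50, 50), leaf_boundaries=np.array([-50.0, 50.0]),
                  leaf_open=np.array([[0.0], [0.0]]), transmission=0.015)
    rec = PhaseSpaceRecord(x=10.0, y=0.0, u=0.0, v=0.0, w=1.0, energy=1.0, weight=1.0)
    out = collimate(rec, ap)
    assert out.weight == pytest.approx(0.015)


def test_collimate_never_increases_weight(rng):
    src = BeamSource(energy="6X", spectrum=((1.0, 1.0),))
    recs = src.sample_batch(rng, 10_000)
    ap = Aperture(jaws=(-30, 30, -30, 30), leaf_boundaries=np.array([-50.0, 0.0, 50.0]),
                  leaf_open=np.array([[-30.0, -10.0], [30.0, 10.0]]), transmission=0.1)
    out = collimate_batch(recs, ap)
    assert np.all(out["wt"] <= recs["wt"] + 1e-12)


def test_open_field_transmission_equals_area_fraction(rng):
    # isotropic-over-window rays: transmitted fraction ~ open-area fraction
    src = BeamSource(energy="6X", spectrum=((1.0, 1.0),), window_halfsize_mm=100.0)
    recs = src.sample_batch(rng, 100_000)
    ap = open_10x10()
    out = collimate_batch(recs, ap)
    frac = len(out) / len(recs)
    expected = (100.0 * 100.0) / (200.0 * 200.0)
    sigma = math.sqrt(expected * (1 - expected) / len(recs))
    assert abs(frac - expected) < 4 * sigma


def test_aperture_open_area():
    ap = open_10x10()
    assert ap.open_area_mm2() == pytest.approx(100.0 * 100.0)
    assert ap.open_bbox() == (-50.0, 50.0, -50.0, 50.0)


# -- MU weighting ------------------------------------------------------------

def test_differential_mu_simple():
    beam = static_beam(mu=200.0)
    beam.control_points[0].cum_weight = 0.0
    beam.control_points[1].cum_weight = 1.0
    plan = VMATPlan(beams=[beam])
    # three-point weights [0, 0.5, 1]
    plan2 = make_plan(PlanRecipe(n_arcs=1, control_points=3, beam_mu=200.0))
    assert np.allclose(differential_mu(plan2)[0], [100.0, 100.0])


def test_differential_mu_uniform_98():
    plan = make_plan(PlanRecipe(n_arcs=1, control_points=98, beam_mu=240.0))
    segs = differential_mu(plan)[0]
    assert len(segs) == 97
    assert np.allclose(segs, 240.0 / 97)
    assert math.fsum(segs) == pytest.approx(240.0, abs=1e-12)


def test_differential_mu_zero_segment():
    plan = make_plan(PlanRecipe(n_arcs=1, control_points=3, beam_mu=100.0))
    for cp, w in zip(plan.beams[0].control_points, (0.0, 0.0, 1.0)):
        cp.cum_weight = w
    segs = differential_mu(plan)[0]
    assert segs[0] == 0.0
    assert segs[1] == pytest.approx(100.0)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
       st.floats(min_value=1.0, max_value=1000.0))
@settings(max_examples=50, deadline=None)
def test_differential_mu_sums_to_beam_mu(increments, mu):
    w = np.concatenate([[0.0], np.cumsum(increments)])
    if w[-1] == 0.0:
        w = np.append(w, 1.0)
    else:
        w = w / w[-1]
    plan = make_plan(PlanRecipe(n_arcs=1, control_points=len(w), beam_mu=mu))
    for cp, wi in zip(plan.beams[0].control_points, w):
        cp.cum_weight = float(wi)
    segs = differential_mu(plan)[0]
    assert math.fsum(segs) == pytest.approx(mu, rel=1e-12)
    assert np.all(segs >= -1e-12)


def test_arc_segments_midpoint():
    plan = make_plan(PlanRecipe(n_arcs=1, control_points=3, gantry_start=350.0,
                                gantry_span=20.0))
    segs = arc_segments(plan.beams[0])
    assert len(segs) == 2
    assert segs[0].gantry_deg == pytest.approx(355.0)  # wraps through 0
    assert segs[1].gantry_deg == pytest.approx(5.0)
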