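import math

import numpy as np
import pytest
from scipy.integrate import quad

from muv.beam import arc_segments
from muv.calibration import default_source, reference_setup
from muv.cross_sections import (
    ME_C2_MEV,
    CrossSectionTable,
    compton_energy_at_angle,
    default_table,
    sample_compton,
    sample_compton_batch,
)
from muv.fixtures import PlanRecipe, make_plan
from muv.geometry import trilinear
from muv.phantom import water_phantom
from muv.transport import (
    DoseResult,
    JobSpec,
    PartialDose,
    allocate_histories,
    estimate_uncertainty,
    merge_partials,
    narrow_beam_transmission,
    read_3ddose,
    read_pardose,
    run_job,
    simulate_arc,
    split_job,
    write_3ddose,
    write_pardose,
)
from tests.conftest import static_beam


# -- cross-section table -----------------------------------------------------

def test_table_total_is_sum_of_parts():
    t = default_table()
    assert np.allclose(t.total, t.photoelectric + t.compton + t.pair, rtol=1e-12)
    assert np.all(t.total > 0)
    assert np.all(np.diff(t.energies) > 0)


def test_water_mu_at_1mev():
    # the packaged table reproduces the standard water value ~0.0707 cm^2/g
    t = default_table()
    assert float(t.mu_rho(2, 1.0)) == pytest.approx(0.0707, abs=0.001)


def test_mu_tr_below_total():
    t = default_table()
    assert np.all(t.mu_tr <= t.total + 1e-15)


# -- Klein-Nishina sampling ---------------------------------------------------

def _kn_pdf(eps, alpha):
    """Unnormalized KN density in eps = E'/E (independent oracle)."""
    t = (1.0 - eps) / (alpha * eps)
    sin2 = t * (2.0 - t)
    return (1.0 / eps + eps) * (1.0 - eps * sin2 / (1.0 + eps**2))


def kn_numeric_moments(energy_mev):
    alpha = energy_mev / ME_C2_MEV
    eps0 = 1.0 / (1.0 + 2.0 * alpha)
    norm, _ = quad(_kn_pdf, eps0, 1.0, args=(alpha,))
    m1, _ = quad(lambda e: e * _kn_pdf(e, alpha), eps0, 1.0, args=())
    cosbar, _ = quad(lambda e: (1.0 - (1.0 - e) / (alpha * e)) * _kn_pdf(e, alpha),
                     eps0, 1.0)
    return m1 / norm, cosbar / norm


def test_compton_edge_backscatter():
    # E = m_e c^2 backscatters to exactly E/3; 0.511 MeV to ~0.1703 MeV
    assert compton_energy_at_angle(ME_C2_MEV, math.pi) == pytest.approx(ME_C2_MEV / 3.0, rel=1e-12)
    assert compton_energy_at_angle(0.511, math.pi) == pytest.approx(0.1703, abs=1e-4)


def test_compton_forward_limit():
    assert compton_energy_at_angle(1.0, 0.0) == pytest.approx(1.0)


def test_compton_energy_bounds(rng):
    e = 1.0
    ep, cos_t = sample_compton_batch(np.full(20_000, e), rng)
    eps0 = 1.0 / (1.0 + 2.0 * e / ME_C2_MEV)
    assert np.all(ep >= e * eps0 - 1e-12)
    assert np.all(ep <= e + 1e-12)
    assert np.all(np.abs(cos_t) <= 1.0 + 1e-12)


def test_compton_moments_vs_numeric_oracle(rng):
    n = 1_000_000
    ep, cos_t = sample_compton_batch(np.full(n, 1.0), rng)
    mean_eps_num, mean_cos_num = kn_numeric_moments(1.0)
    se_eps = np.std(ep) / math.sqrt(n)
    se_cos = np.std(cos_t) / math.sqrt(n)
    assert abs(np.mean(ep) - mean_eps_num) < 3 * se_eps
    assert abs(np.mean(cos_t) - mean_cos_num) < 3 * se_cos


def test_sample_compton_scalar(rng):
    ep, theta = sample_compton(1.0, rng)
    assert 0.0 <= theta <= math.pi
    # kinematic consistency between sampled energy and angle
    assert ep == pytest.approx(compton_energy_at_angle(1.0, theta), rel=1e-9)


def test_sample_compton_rejects_nonpositive(rng):
    with pytest.raises(ValueError):
        sample_compton(-1.0, rng)


# -- job splitting ------------------------------------------------------------

def test_split_1e7_histories_into_1e5_jobs():
    jobs = split_job(10_000_000, 100, base_seed=0)
    assert len(jobs) == 100
    assert all(j.histories == 100_000 for j in jobs)


def test_split_remainder_rule():
    jobs = split_job(10, 3, base_seed=0)
    assert [j.histories for j in jobs] == [4, 3, 3]
    assert [j.offset for j in jobs] == [0, 4, 7]


def test_split_320_jobs():
    jobs = split_job(10**9, 320, base_seed=0)
    assert len(jobs) == 320
    assert all(j.histories == 3_125_000 for j in jobs)


def test_split_seeds_unique():
    jobs = split_job(1000, 10, base_seed=7)
    seeds = [j.seed for j in jobs]
    assert len(set(seeds)) == 10
    assert seeds == [7 + k for k in range(10)]


def test_split_too_many_jobs():
    with pytest.raises(ValueError):
        split_job(5, 10, base_seed=0)


def test_allocate_histories_largest_remainder():
    out = allocate_histories(10, np.array([1.0, 1.0, 1.0]))
    assert out.sum() == 10
    assert sorted(out.tolist()) == [3, 3, 4]
    assert np.array_equal(allocate_histories(100, np.array([0.0, 1.0])), [0, 100])
    assert np.array_equal(allocate_histories(100, np.zeros(3)), [0, 0, 0])


# -- engine -------------------------------------------------------------------

def _ref_run(histories, n_jobs=1, seed=21, spacing=20.0):
    setup = reference_setup("6X", spacing_mm=spacing)
    return simulate_arc(setup.phantom, default_source("6X"),
                        setup.plan.beams[0], histories=histories,
                        n_jobs=n_jobs, base_seed=seed), setup


def test_narrow_beam_attenuation_oracle():
    # closed-form: exp(-mu * t) for 10 cm water with the packaged coefficient
    ph = water_phantom(side_mm=100.0, spacing_mm=5.0)
    frac, sigma = narrow_beam_transmission(ph, 1.0, 100_000, seed=1,
                                           origin_mm=np.array([0.0, -50.0, 0.0]),
                                           direction=np.array([0.0, 1.0, 0.0]))
    mu = float(default_table().mu_rho(2, 1.0))  # density 1.0 override
    expected = math.exp(-mu * 10.0)
    assert expected == pytest.approx(math.exp(-0.707), abs=0.01)
    assert abs(frac - expected) < 3 * sigma


def test_run_job_deterministic():
    setup = reference_setup("6X", spacing_mm=20.0)
    segs = arc_segments(setup.plan.beams[0])
    spec = JobSpec(arc_id=0, histories=5000, base_seed=3, phantom=setup.phantom,
                   source=default_source("6X"), segments=segs)
    a = run_job(spec)
    b = run_job(spec)
    assert np.array_equal(a.sums, b.sums)
    assert np.array_equal(a.sumsq, b.sumsq)


def test_run_job_unresolved_references():
    with pytest.raises(ValueError, match="unresolved"):
        run_job(JobSpec(arc_id=0, histories=10, base_seed=0))


def test_zero_mu_segment_gets_zero_histories():
    plan = make_plan(PlanRecipe(n_arcs=1, control_points=3, beam_mu=100.0))
    for cp, w in zip(plan.beams[0].control_points, (0.0, 0.0, 1.0)):
        cp.cum_weight = w
    segs = arc_segments(plan.beams[0])
    alloc = allocate_histories(1000, np.array([s.mu for s in segs]))
    assert alloc[0] == 0 and alloc[1] == 1000


def test_split_merge_equivalence():
    r1, _ = _ref_run(20_000, n_jobs=1)
    r2, _ = _ref_run(20_000, n_jobs=2)
    mask = (r1.dose > 0) | (r2.dose > 0)
    rel = np.abs(r1.dose[mask] - r2.dose[mask]) / np.maximum(r1.dose[mask], 1e-300)
    assert np.max(rel) <= 1e-12


def test_merge_weights_by_histories():
    geom = water_phantom(side_mm=20.0, spacing_mm=10.0).geometry
    a = PartialDose(sums=np.full(geom.shape, 1.0), sumsq=np.full(geom.shape, 1.0),
                    histories=10_000, geometry=geom)
    b = PartialDose(sums=np.full(geom.shape, 9.0), sumsq=np.full(geom.shape, 9.0),
                    histories=90_000, geometry=geom)
    merged = merge_partials([a, b])
    assert np.allclose(merged.dose, 10.0 / 100_000)  # not (0.1+0.1)/2 by file count


def test_merge_single_part():
    geom = water_phantom(side_mm=20.0, spacing_mm=10.0).geometry
    a = PartialDose(sums=np.full(geom.shape, 3.0), sumsq=np.full(geom.shape, 2.0),
                    histories=100, geometry=geom)
    merged = merge_partials([a])
    assert np.allclose(merged.dose, 0.03)


def test_merge_geometry_mismatch():
    g1 = water_phantom(side_mm=20.0, spacing_mm=10.0).geometry
    g2 = water_phantom(side_mm=40.0, spacing_mm=10.0).geometry
    a = PartialDose(sums=np.zeros(g1.shape), sumsq=np.zeros(g1.shape),
                    histories=1, geometry=g1)
    b = PartialDose(sums=np.zeros(g2.shape), sumsq=np.zeros(g2.shape),
                    histories=1, geometry=g2)
    with pytest.raises(ValueError, match="geometry"):
        merge_partials([a, b])


def test_merge_order_independent():
    parts = []
    setup = reference_setup("6X", spacing_mm=20.0)
    segs = arc_segments(setup.plan.beams[0])
    for j in split_job(15_000, 3, 5, phantom=setup.phantom,
                       source=default_source("6X"), segments=segs):
        parts.append(run_job(j))
    a = merge_partials(parts)
    b = merge_partials(parts)  # fixed index order: bitwise-stable
    assert np.array_equal(a.dose, b.dose)


# -- uncertainty --------------------------------------------------------------

def test_uncertainty_constant_deposit_is_zero():
    geom = water_phantom(side_mm=20.0, spacing_mm=10.0).geometry
    n = 100
    d = 2.0
    part = PartialDose(sums=np.full(geom.shape, n * d),
                       sumsq=np.full(geom.shape, n * d**2),
                       histories=n, geometry=geom)
    rel = estimate_uncertainty(part)
    assert np.allclose(rel, 0.0, atol=1e-9)


def test_uncertainty_unhit_voxel_flagged():
    geom = water_phantom(side_mm=20.0, spacing_mm=10.0).geometry
    sums = np.zeros(geom.shape)
    sums[0, 0, 0] = 5.0
    part = PartialDose(sums=sums, sumsq=sums**2 / 10, histories=10, geometry=geom)
    rel = estimate_uncertainty(part)
    assert np.isnan(rel[1, 1, 1])
    assert np.isfinite(rel[0, 0, 0])


def test_uncertainty_quadrupling_halves_sigma():
    r1, setup = _ref_run(250_000, seed=13)
    r4, _ = _ref_run(1_000_000, seed=13)
    sel = r4.dose >= 0.5 * np.nanmax(r4.dose)
    m1 = float(np.nanmedian(r1.rel_uncertainty[sel]))
    m4 = float(np.nanmedian(r4.rel_uncertainty[sel]))
    assert m4 / m1 == pytest.approx(0.5, abs=0.05)


# -- physics invariants -------------------------------------------------------

def test_energy_bookkeeping():
    r, _ = _ref_run(50_000)
    assert r.deposited_energy_mev <= r.launched_energy_mev + 1e-6
    assert r.deposited_energy_mev > 0


def test_mirror_symmetry():
    ph = water_phantom(side_mm=200.0, spacing_mm=20.0)
    beam = static_beam(halfsize_mm=40.0)
    res = simulate_arc(ph, default_source("6X"), beam, histories=400_000,
                       n_jobs=2, base_seed=17)
    dose = res.dose
    rel = res.rel_uncertainty
    flipped = dose[:, :, ::-1]
    flipped_rel = rel[:, :, ::-1]
    sel = (dose > 0) & (flipped > 0) & (dose >= 0.3 * np.nanmax(dose))
    sigma = np.sqrt((dose * np.nan_to_num(rel)) ** 2
                    + (flipped * np.nan_to_num(flipped_rel)) ** 2)
    z = np.abs(dose[sel] - flipped[sel]) / sigma[sel]
    # allow a small fraction of 3-sigma excursions (multiple comparisons)
    assert np.mean(z < 3.0) > 0.97


def test_mu_scales_dose_linearly():
    from muv.calibration import CalibrationFactor, apply_calibration

    r, _ = _ref_run(20_000)
    f = CalibrationFactor(value=1e14, energy="6X")
    d1 = apply_calibration(r, f, mu=100.0, energy="6X")
    d2 = apply_calibration(r, f, mu=200.0, energy="6X")
    assert np.allclose(d2, 2.0 * d1)


# -- pardose / 3ddose files ---------------------------------------------------

def test_pardose_round_trip(tmp_path):
    r, setup = _ref_run(5000)
    segs = arc_segments(setup.plan.beams[0])
    spec = JobSpec(arc_id=0, histories=5000, base_seed=21, phantom=setup.phantom,
                   source=default_source("6X"), segments=segs)
    part = run_job(spec)
    write_pardose(tmp_path / "a.pardose", part)
    loaded = read_pardose(tmp_path / "a.pardose")
    assert loaded.histories == part.histories
    assert np.array_equal(loaded.sums, part.sums)
    assert np.array_equal(loaded.sumsq, part.sumsq)
    assert loaded.geometry.approx_equal(part.geometry)


def test_3ddose_round_trip(tmp_path):
    r, _ = _ref_run(5000)
    write_3ddose(tmp_path / "a.3ddose", r)
    loaded = read_3ddose(tmp_path / "a.3ddose")
    assert loaded.geometry.shape == r.geometry.shape
    assert np.allclose(loaded.dose, r.dose, rtol=1e-6, atol=1e-25)
    lines = (tmp_path / "a.3ddose").read_text().splitlines()
    nx, ny, nz = (int(v) for v in lines[0].split())
    assert (nz, ny, nx) == r.geometry.shape
    assert len(lines[1].split()) == nx + 1  # x boundaries in cm
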