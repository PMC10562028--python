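"""Desk-scale Monte Carlo photon dose engine.

Photon-only transport through the voxel phantom using Woodcock (delta)
tracking against an energy-dependent majorant cross section, with kerma
approximation energy deposition: at each real interaction the energy
transferred to electrons is deposited locally.  Compton scattering uses
exact Klein-Nishina sampling; photoelectric absorption terminates the
photon; pair production above 1.022 MeV deposits the excess and emits two
back-to-back 0.511 MeV annihilation photons; photons below the 10 keV
cutoff are absorbed locally.

Reproducibility: histories carry absolute indices and are processed in
fixed-size batches aligned to those indices, with an RNG stream keyed by
``(base_seed, segment, batch_start)``.  A run split across jobs whose
boundaries align with batch edges therefore reproduces the unsplit run's
per-voxel sums up to floating-point summation order.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field

import numpy as np

from .beam import BeamSource, Segment, arc_segments, bev_to_patient
from .cross_sections import (
    CrossSectionTable,
    ENERGY_CUTOFF_MEV,
    ME_C2_MEV,
    PAIR_THRESHOLD_MEV,
    default_table,
    sample_compton_batch,
)
from .dicom_io import ArcBeam
from .geometry import Geometry
from .phantom import VoxelPhantom

GY_PER_MEV = 1.602176634e-13  # J per MeV; voxel masses are in kg
HISTORY_BATCH = 5000  # absolute-index aligned RNG batch size

# re-export: Compton sampling is part of this module's contract
from .cross_sections import sample_compton  # noqa: E402,F401


# ---------------------------------------------------------------------------
# job specification and splitting
# ---------------------------------------------------------------------------

@dataclass
class JobSpec:
    """One parallel slice of an arc simulation.

    ``offset`` is the absolute index of this job's first history within the
    arc's ``arc_total`` histories; seeds are ``base_seed + job_index``.
    """

    arc_id: int
    histories: int
    base_seed: int
    job_index: int = 0
    offset: int = 0
    arc_total: int | None = None
    phantom: VoxelPhantom | None = None
    source: BeamSource | None = None
    segments: list[Segment] | None = None
    scatter: bool = True

    def __post_init__(self) -> None:
        if self.histories <= 0:
            raise ValueError("histories must be positive")
        if self.arc_total is None:
            self.arc_total = self.offset + self.histories

    @property
    def seed(self) -> int:
        return self.base_seed + self.job_index


def split_job(total_histories: int, n_jobs: int, base_seed: int,
              **refs) -> list[JobSpec]:
    """Split an arc simulation into near-equal jobs with unique seeds.

    Per-job histories differ by at most one and sum exactly to the total;
    job *k* receives seed ``base_seed + k``.
    """
    if n_jobs < 1:
        raise ValueError("n_jobs must be >= 1")
    if n_jobs > total_histories:
        raise ValueError(f"cannot split {total_histories} histories into {n_jobs} jobs")
    q, r = divmod(int(total_histories), int(n_jobs))
    sizes = [q + 1] * r + [q] * (n_jobs - r)
    jobs = []
    offset = 0
    for k, n in enumerate(sizes):
        jobs.append(JobSpec(arc_id=refs.get("arc_id", 0), histories=n,
                            base_seed=base_seed, job_index=k, offset=offset,
                            arc_total=int(total_histories),
                            phantom=refs.get("phantom"), source=refs.get("source"),
                            segments=refs.get("segments"),
                            scatter=refs.get("scatter", True)))
        offset += n
    return jobs


def allocate_histories(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder proportional allocation of histories to segments."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if s == 0:
        return np.zeros(len(w), dtype=np.int64)
    shares = total * w / s
    base = np.floor(shares).astype(np.int64)
    remainder = int(total - base.sum())
    if remainder:
        frac = shares - base
        order = np.argsort(-frac, kind="stable")
        base[order[:remainder]] += 1
    return base


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class PartialDose:
    """Per-job accumulator: per-voxel dose sums and squared sums (Gy/particle
    basis) plus the history count and energy bookkeeping (MeV)."""

    sums: np.ndarray  # (nz, ny, nx) sum over histories of per-history dose
    sumsq: np.ndarray
    histories: int
    geometry: Geometry
    launched_energy_mev: float = 0.0
    deposited_energy_mev: float = 0.0

    def __post_init__(self) -> None:
        if self.histories <= 0:
            raise ValueError("histories must be positive")
        if np.any(self.sums < 0) or not np.all(np.isfinite(self.sums)):
            raise ValueError("sums must be finite and non-negative")


@dataclass
class DoseResult:
    """Merged engine output: dose in Gy/particle with relative uncertainty."""

    dose: np.ndarray
    rel_uncertainty: np.ndarray  # NaN where the voxel was never hit
    histories: int
    geometry: Geometry
    launched_energy_mev: float = 0.0
    deposited_energy_mev: float = 0.0
    energy: str | None = None  # beam energy label, when known


def estimate_uncertainty(obj: PartialDose | DoseResult) -> np.ndarray:
    """History-based per-voxel relative sigma; NaN where dose is zero."""
    if isinstance(obj, DoseResult):
        return obj.rel_uncertainty
    n = obj.histories
    if n < 2:
        raise ValueError("need at least 2 histories for an uncertainty estimate")
    mean = obj.sums / n
    var = (obj.sumsq / n - mean**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(var) / mean
    rel[mean <= 0] = np.nan
    return rel


def merge_partials(parts: list[PartialDose]) -> DoseResult:
    """Combine per-job accumulators, weighting by histories.

    Summation runs in fixed index order so the merge is independent of how
    the parts were grouped (up to float round-off).
    """
    if not parts:
        raise ValueError("nothing to merge")
    geom = parts[0].geometry
    for p in parts[1:]:
        if not geom.approx_equal(p.geometry):
            raise ValueError("geometry mismatch between partial doses")
    sums = np.zeros_like(parts[0].sums)
    sumsq = np.zeros_like(parts[0].sumsq)
    for p in parts:
        sums += p.sums
        sumsq += p.sumsq
    n = sum(p.histories for p in parts)
    merged = PartialDose(sums=sums, sumsq=sumsq, histories=n, geometry=geom,
                         launched_energy_mev=sum(p.launched_energy_mev for p in parts),
                         deposited_energy_mev=sum(p.deposited_energy_mev for p in parts))
    return DoseResult(dose=sums / n, rel_uncertainty=estimate_uncertainty(merged),
                      histories=n, geometry=geom,
                      launched_energy_mev=merged.launched_energy_mev,
                      deposited_energy_mev=merged.deposited_energy_mev)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class _Tracker:
    """Precomputed per-(phantom, table) lookups for Woodcock tracking."""

    def __init__(self, phantom: VoxelPhantom, table: CrossSectionTable):
        self.phantom = phantom
        self.table = table
        self.lo, self.hi = phantom.geometry.bounds()
        self.spacing = np.array(phantom.geometry.spacing)
        nz, ny, nx = phantom.geometry.shape
        self.shape = (nz, ny, nx)
        self.material = phantom.material.ravel()
        self.density = phantom.density.ravel()
        rho_max = phantom.max_density_per_material()
        # majorant linear attenuation (1/cm) on the table's energy grid
        self.maj_energies = table.energies
        self.majorant = np.max(table.total * rho_max[:, None], axis=0)
        vol_cm3 = np.prod(self.spacing) / 1000.0
        self.mass_kg = self.density * vol_cm3 / 1000.0

    def majorant_at(self, energy: np.ndarray) -> np.ndarray:
        e = np.clip(energy, self.maj_energies[0], self.maj_energies[-1])
        return np.interp(np.log(e), np.log(self.maj_energies), self.majorant)

    def voxel_flat(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Flat voxel index and an inside-mask for patient-space positions."""
        idx = np.floor((pos - (self.lo)) / self.spacing).astype(np.int64)
        nz, ny, nx = self.shape
        inside = (
            (idx[:, 0] >= 0) & (idx[:, 0] < nx)
            & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
            & (idx[:, 2] >= 0) & (idx[:, 2] < nz)
        )
        ic = np.clip(idx, 0, [nx - 1, ny - 1, nz - 1])
        flat = (ic[:, 2] * ny + ic[:, 1]) * nx + ic[:, 0]
        return flat, inside

    def enter_box(self, pos: np.ndarray, direction: np.ndarray):
        """Advance rays to their phantom-entry point; returns mask of hits."""
        eps = 1e-9
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / direction
        t1 = (self.lo - pos) * inv
        t2 = (self.hi - pos) * inv
        tmin = np.nanmax(np.minimum(t1, t2), axis=1)
        tmax = np.nanmin(np.maximum(t1, t2), axis=1)
        hit = (tmax > np.maximum(tmin, 0.0) + eps)
        t_entry = np.maximum(tmin, 0.0) + 1e-6
        newpos = pos + direction * t_entry[:, None]
        return newpos, hit


def _rotate_directions(d: np.ndarray, cos_t: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vectors by polar angle (cos_t) and uniform azimuth."""
    n = len(d)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    # orthonormal frame around each direction
    helper = np.where(np.abs(d[:, 2:3]) < 0.99,
                      np.tile([0.0, 0.0, 1.0], (n, 1)),
                      np.tile([1.0, 0.0, 0.0], (n, 1)))
    e1 = np.cross(helper, d)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    out = (cos_t[:, None] * d
           + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _batch_seed(base_seed: int, arc_id: int, segment: int, batch_start: int) -> list[int]:
    return [int(base_seed) & 0xFFFFFFFF, arc_id, segment, batch_start]


def _simulate_batch(tracker: _Tracker, source: BeamSource, segment: Segment,
                    rng: np.random.Generator, n: int, hist_offset: int,
                    scatter: bool):
    """Transport one batch; returns (hist_ids, voxel_flat, edep_MeV, launched)."""
    table = tracker.table
    window = None
    if source.phase_space is None and segment.aperture.transmission == 0.0:
        # importance-sample the emission window down to the open region
        # (+5 mm margin); record weights keep the fluence normalization
        bx1, bx2, by1, by2 = segment.aperture.open_bbox()
        if bx2 <= bx1 or by2 <= by1:
            return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0), 0.0)
        window = (bx1 - 5.0, bx2 + 5.0, by1 - 5.0, by2 + 5.0)
    recs = source.sample_batch(rng, n, window=window)
    hist = hist_offset + np.arange(n, dtype=np.int64)
    # collimate with explicit index tracking (histories absorbed at the
    # aperture still count toward the per-particle normalization)
    t = source.plane_mm / recs["w"]
    xi = recs["x"] + recs["u"] * t
    yi = recs["y"] + recs["v"] * t
    inside = segment.aperture.contains(xi, yi)
    weight = recs["wt"].astype(np.float64)
    if segment.aperture.transmission == 0.0:
        keep = inside
    else:
        keep = np.ones(n, dtype=bool)
        weight[~inside] *= segment.aperture.transmission
    recs, weight, hist = recs[keep], weight[keep], hist[keep]
    launched = float(np.sum(recs["E"] * weight))
    if len(recs) == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0), launched)
    rot, _focal = bev_to_patient(segment.gantry_deg)
    bev_pos = np.column_stack([recs["x"], recs["y"],
                               np.full(len(recs), -source.plane_mm)])
    pos = bev_pos @ rot.T
    direction = np.column_stack([recs["u"], recs["v"], recs["w"]]) @ rot.T
    energy = recs["E"].astype(np.float64)

    pos, hit = tracker.enter_box(pos, direction)
    alive = hit
    pos, direction = pos[alive], direction[alive]
    energy, weight, hist = energy[alive], weight[alive], hist[alive]

    dep_hist: list[np.ndarray] = []
    dep_vox: list[np.ndarray] = []
    dep_e: list[np.ndarray] = []
    pend: list[tuple[np.ndarray, ...]] = []

    def deposit(h, v, e):
        if len(h):
            dep_hist.append(h)
            dep_vox.append(v)
            dep_e.append(e)

    while len(pos) or pend:
        if not len(pos):
            p2, d2, e2, w2, h2 = pend.pop()
            pos, direction, energy, weight, hist = p2, d2, e2, w2, h2
            continue
        maj = tracker.majorant_at(energy)  # 1/cm
        step_mm = 10.0 * (-np.log(rng.random(len(pos)))) / maj
        pos = pos + direction * step_mm[:, None]
        vox, inside = tracker.voxel_flat(pos)
        if not np.any(inside):
            pos = pos[:0]
            direction, energy, weight, hist = direction[:0], energy[:0], weight[:0], hist[:0]
            continue
        pos, direction = pos[inside], direction[inside]
        energy, weight, hist, vox = energy[inside], weight[inside], hist[inside], vox[inside]
        mat = tracker.material[vox]
        mu_real = table.mu_rho(mat, energy, "total") * tracker.density[vox]
        maj = tracker.majorant_at(energy)
        real = rng.random(len(pos)) < mu_real / maj
        if not np.any(real):
            continue
        # split off the interacting photons
        rpos, rdir = pos[real], direction[real]
        re_, rw, rh, rv = energy[real], weight[real], hist[real], vox[real]
        rmat = mat[real]
        pos, direction = pos[~real], direction[~real]
        energy, weight, hist = energy[~real], weight[~real], hist[~real]

        if not scatter:
            deposit(rh, rv, re_ * rw)
            continue

        f_pe, f_co, f_pp = table.partial_fractions(rmat, re_)
        u = rng.random(len(re_))
        is_pe = u < f_pe
        is_co = (~is_pe) & (u < f_pe + f_co)
        is_pp = ~(is_pe | is_co)

        deposit(rh[is_pe], rv[is_pe], re_[is_pe] * rw[is_pe])

        if np.any(is_co):
            e_new, cos_t = sample_compton_batch(re_[is_co], rng)
            deposit(rh[is_co], rv[is_co], (re_[is_co] - e_new) * rw[is_co])
            d_new = _rotate_directions(rdir[is_co], cos_t, rng)
            below = e_new < ENERGY_CUTOFF_MEV
            if np.any(below):
                deposit(rh[is_co][below], rv[is_co][below],
                        e_new[below] * rw[is_co][below])
            keep = ~below
            pos = np.concatenate([pos, rpos[is_co][keep]])
            direction = np.concatenate([direction, d_new[keep]])
            energy = np.concatenate([energy, e_new[keep]])
            weight = np.concatenate([weight, rw[is_co][keep]])
            hist = np.concatenate([hist, rh[is_co][keep]])

        if np.any(is_pp):
            k = int(np.sum(is_pp))
            deposit(rh[is_pp], rv[is_pp], (re_[is_pp] - PAIR_THRESHOLD_MEV) * rw[is_pp])
            d_new = _isotropic_directions(k, rng)
            ann_e = np.full(k, ME_C2_MEV)
            pos = np.concatenate([pos, rpos[is_pp]])
            direction = np.concatenate([direction, d_new])
            energy = np.concatenate([energy, ann_e])
            weight = np.concatenate([weight, rw[is_pp]])
            hist = np.concatenate([hist, rh[is_pp]])
            pend.append((rpos[is_pp].copy(), -d_new, ann_e.copy(),
                         rw[is_pp].copy(), rh[is_pp].copy()))

    if dep_hist:
        return (np.concatenate(dep_hist), np.concatenate(dep_vox),
                np.concatenate(dep_e), launched)
    return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0), launched)


def run_job(spec: JobSpec, table: CrossSectionTable | None = None) -> PartialDose:
    """Simulate one job deterministically and return its accumulator.

    Histories are allocated to segments proportionally to differential MU
    over the whole arc (largest remainder), so every job of a split agrees
    on the absolute segment boundaries.
    """
    if spec.phantom is None or spec.source is None or spec.segments is None:
        missing = [k for k in ("phantom", "source", "segments") if getattr(spec, k) is None]
        raise ValueError(f"job references unresolved: {missing}")
    table = table or default_table()
    tracker = _Tracker(spec.phantom, table)
    nvox = spec.phantom.geometry.nvoxels
    sums = np.zeros(nvox)
    sumsq = np.zeros(nvox)
    launched = 0.0

    mus = np.array([s.mu for s in spec.segments])
    seg_alloc = allocate_histories(spec.arc_total, mus)
    seg_starts = np.concatenate([[0], np.cumsum(seg_alloc)])
    job_lo, job_hi = spec.offset, spec.offset + spec.histories

    for s, seg in enumerate(spec.segments):
        a = max(int(seg_starts[s]), job_lo)
        b = min(int(seg_starts[s + 1]), job_hi)
        pos = a
        while pos < b:
            batch_end = min(((pos // HISTORY_BATCH) + 1) * HISTORY_BATCH, b)
            nb = batch_end - pos
            rng = np.random.default_rng(_batch_seed(spec.base_seed, spec.arc_id, s, pos))
            h, v, e, lau = _simulate_batch(tracker, spec.source, seg, rng, nb,
                                           pos, spec.scatter)
            launched += lau
            if len(h):
                # per-history per-voxel totals for history-by-history variance
                key = h.astype(np.int64) * nvox + v
                uniq, inv = np.unique(key, return_inverse=True)
                etot = np.zeros(len(uniq))
                np.add.at(etot, inv, e)
                uvox = (uniq % nvox).astype(np.int64)
                d = etot * GY_PER_MEV / tracker.mass_kg[uvox]
                np.add.at(sums, uvox, d)
                np.add.at(sumsq, uvox, d**2)
            pos = batch_end

    shape = spec.phantom.geometry.shape
    vol_mass = tracker.mass_kg  # kg per voxel (flat)
    deposited = float(np.sum(sums * vol_mass) / GY_PER_MEV)
    return PartialDose(sums=sums.reshape(shape), sumsq=sumsq.reshape(shape),
                       histories=spec.histories, geometry=spec.phantom.geometry,
                       launched_energy_mev=launched,
                       deposited_energy_mev=deposited)


def simulate_arc(phantom: VoxelPhantom, source: BeamSource, beam: ArcBeam,
                 histories: int, n_jobs: int = 1, base_seed: int = 0,
                 transmission: float = 0.0,
                 table: CrossSectionTable | None = None) -> DoseResult:
    """Split, run and merge a whole-arc simulation (Gy/particle output)."""
    segments = arc_segments(beam, transmission=transmission)
    jobs = split_job(histories, n_jobs, base_seed, phantom=phantom,
                     source=source, segments=segments)
    parts = [run_job(j, table=table) for j in jobs]
    result = merge_partials(parts)
    result.energy = beam.energy
    return result


# ---------------------------------------------------------------------------
# narrow-beam (attenuation-only) experiment
# ---------------------------------------------------------------------------

def narrow_beam_transmission(phantom: VoxelPhantom, energy_mev: float,
                             histories: int, seed: int,
                             origin_mm: np.ndarray, direction: np.ndarray,
                             table: CrossSectionTable | None = None):
    """Fraction of pencil-beam photons crossing the phantom uninteracted.

    Woodcock tracking with scatter scoring off: any real interaction
    removes the photon.  Returns ``(fraction, binomial_sigma)``.
    """
    table = table or default_table()
    tracker = _Tracker(phantom, table)
    rng = np.random.default_rng(seed)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pos = np.tile(np.asarray(origin_mm, dtype=float), (histories, 1))
    direction_arr = np.tile(d, (histories, 1))
    pos, hit = tracker.enter_box(pos, direction_arr)
    if not np.all(hit):
        raise ValueError("pencil beam misses the phantom")
    energy = np.full(histories, float(energy_mev))
    transmitted = 0
    alive = np.arange(histories)
    while len(alive):
        maj = tracker.majorant_at(energy[alive])
        step_mm = 10.0 * (-np.log(rng.random(len(alive)))) / maj
        pos[alive] += direction_arr[alive] * step_mm[:, None]
        vox, inside = tracker.voxel_flat(pos[alive])
        exited = ~inside
        transmitted += int(np.sum(exited))
        keep = alive[inside]
        vox = vox[inside]
        if not len(keep):
            break
        mu_real = table.mu_rho(tracker.material[vox], energy[keep], "total") \
            * tracker.density[vox]
        maj = tracker.majorant_at(energy[keep])
        interacted = rng.random(len(keep)) < mu_real / maj
        alive = keep[~interacted]
    frac = transmitted / histories
    sigma = float(np.sqrt(max(frac * (1 - frac), 1e-12) / histories))
    return frac, sigma


# ---------------------------------------------------------------------------
# pardose / 3ddose files
# ---------------------------------------------------------------------------

_PARDOSE_MAGIC = b"MUVPARD1"


def write_pardose(path, part: PartialDose) -> None:
    """Documented binary layout: header (magic, geometry hash, histories,
    shape, origin, spacing, energy bookkeeping) + two float64 arrays."""
    g = part.geometry
    geo_hash = hashlib.sha256(
        struct.pack("<3d3d3q", *g.origin, *g.spacing, *g.shape)).digest()[:16]
    with open(path, "wb") as fh:
        fh.write(_PARDOSE_MAGIC)
        fh.write(geo_hash)
        fh.write(struct.pack("<Q", part.histories))
        fh.write(struct.pack("<3q", *g.shape))
        fh.write(struct.pack("<3d", *g.origin))
        fh.write(struct.pack("<3d", *g.spacing))
        fh.write(struct.pack("<2d", part.launched_energy_mev, part.deposited_energy_mev))
        fh.write(np.ascontiguousarray(part.sums, dtype="<f8").tobytes())
        fh.write(np.ascontiguousarray(part.sumsq, dtype="<f8").tobytes())


def read_pardose(path) -> PartialDose:
    with open(path, "rb") as fh:
        if fh.read(8) != _PARDOSE_MAGIC:
            raise ValueError(f"{path}: not a pardose file")
        fh.read(16)  # geometry hash (informational)
        histories = struct.unpack("<Q", fh.read(8))[0]
        shape = struct.unpack("<3q", fh.read(24))
        origin = struct.unpack("<3d", fh.read(24))
        spacing = struct.unpack("<3d", fh.read(24))
        launched, deposited = struct.unpack("<2d", fh.read(16))
        n = int(np.prod(shape))
        sums = np.frombuffer(fh.read(8 * n), dtype="<f8").reshape(shape).copy()
        sumsq = np.frombuffer(fh.read(8 * n), dtype="<f8").reshape(shape).copy()
    geom = Geometry(origin=origin, spacing=spacing, shape=tuple(int(s) for s in shape))
    return PartialDose(sums=sums, sumsq=sumsq, histories=int(histories), geometry=geom,
                       launched_energy_mev=launched, deposited_energy_mev=deposited)


def write_3ddose(path, result: DoseResult) -> None:
    """EGSnrc text convention: counts, x/y/z boundaries (cm), doses, errors."""
    g = result.geometry
    nz, ny, nx = g.shape
    with open(path, "w") as fh:
        fh.write(f"{nx} {ny} {nz}\n")
        for axis in (0, 1, 2):
            fh.write(" ".join(f"{b / 10.0:.6f}" for b in g.edges(axis)) + "\n")
        fh.write(" ".join(f"{v:.8e}" for v in result.dose.ravel()) + "\n")
        err = np.nan_to_num(result.rel_uncertainty, nan=0.9999)
        fh.write(" ".join(f"{v:.6f}" for v in err.ravel()) + "\n")


def read_3ddose(path) -> DoseResult:
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(tokens)
    nx, ny, nz = (int(next(it)) for _ in range(3))
    xb = np.array([float(next(it)) for _ in range(nx + 1)]) * 10.0
    yb = np.array([float(next(it)) for _ in range(ny + 1)]) * 10.0
    zb = np.array([float(next(it)) for _ in range(nz + 1)]) * 10.0
    dose = np.array([float(next(it)) for _ in range(nx * ny * nz)]).reshape(nz, ny, nx)
    err = np.array([float(next(it)) for _ in range(nx * ny * nz)]).reshape(nz, ny, nx)
    geom = Geometry(origin=(float(xb[0] + (xb[1] - xb[0]) / 2),
                            float(yb[0] + (yb[1] - yb[0]) / 2),
                            float(zb[0] + (zb[1] - zb[0]) / 2)),
                    spacing=(float(xb[1] - xb[0]), float(yb[1] - yb[0]),
                             float(zb[1] - zb[0])),
                    shape=(nz, ny, nx))
    return DoseResult(dose=dose, rel_uncertainty=err, histories=0, geometry=geom)
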