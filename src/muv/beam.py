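"""Photon source handling: phase space files, a parametric emulator, and
per-control-point collimation.

Beam's-eye-view (BEV) frame: origin at the isocenter, +z pointing
*downstream* (from the focal spot toward the patient), so the focal spot
sits at z = -SAD and the phase-space plane at z = -(plane distance above
isocenter).  Record positions (x, y) live on that plane; direction cosines
satisfy u^2+v^2+w^2 = 1 with w > 0.

The multi-leaf collimator is an ideal 2-D aperture at the isocenter plane
with a single global transmission factor for blocked rays; leaf-end and
tongue-and-groove effects are deliberately not modeled.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dicom_io import ArcBeam, ControlPoint, VMATPlan

SAD_MM = 1000.0
DEFAULT_PLANE_MM = 450.0  # phase-space plane height above isocenter

PHSP_MAGIC = b"MUVPHSP1"
PHSP_RECORD_DTYPE = np.dtype(
    [("x", "<f4"), ("y", "<f4"), ("u", "<f4"), ("v", "<f4"), ("w", "<f4"),
     ("E", "<f4"), ("wt", "<f4"), ("type", "u1")]
)
PHOTON = 0


# ---------------------------------------------------------------------------
# phase space
# ---------------------------------------------------------------------------

@dataclass
class PhaseSpaceRecord:
    x: float
    y: float
    u: float
    v: float
    w: float
    energy: float
    weight: float
    ptype: int = PHOTON

    def __post_init__(self) -> None:
        norm = self.u**2 + self.v**2 + self.w**2
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"direction cosines not normalized: |d|^2 = {norm}")
        if self.w <= 0:
            raise ValueError("record must travel downstream (w > 0)")
        if self.energy <= 0 or self.weight <= 0:
            raise ValueError("energy and weight must be positive")


@dataclass
class PhaseSpaceSet:
    """Header plus (optionally sparse) particle records.

    In sparse mode only the declared count is kept — used for count
    arithmetic on files too large to materialize.
    """

    count: int
    energy: str
    plane_mm: float = DEFAULT_PLANE_MM
    records: np.ndarray | None = None  # PHSP_RECORD_DTYPE

    def __post_init__(self) -> None:
        if self.records is not None:
            self.records = np.asarray(self.records, dtype=PHSP_RECORD_DTYPE)
            if len(self.records) != self.count:
                raise ValueError(
                    f"declared count {self.count} != record count {len(self.records)}"
                )

    @property
    def sparse(self) -> bool:
        return self.records is None


_HEADER_STRUCT = struct.Struct("<8sIQ16sfB3x")


def write_phase_space(path, ps: PhaseSpaceSet) -> None:
    """Serialize to the package's fixed-width little-endian binary layout."""
    with open(path, "wb") as fh:
        fh.write(_HEADER_STRUCT.pack(PHSP_MAGIC, 1, ps.count,
                                     ps.energy.encode("ascii").ljust(16, b"\x00"),
                                     ps.plane_mm, 1 if ps.sparse else 0))
        if not ps.sparse:
            fh.write(ps.records.tobytes())


def read_phase_space(path) -> PhaseSpaceSet:
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_STRUCT.size)
        magic, version, count, label, plane, sparse = _HEADER_STRUCT.unpack(header)
        if magic != PHSP_MAGIC:
            raise ValueError(f"{path}: not a phase-space file")
        energy = label.rstrip(b"\x00").decode("ascii")
        if sparse:
            return PhaseSpaceSet(count=count, energy=energy, plane_mm=plane)
        records = np.frombuffer(fh.read(), dtype=PHSP_RECORD_DTYPE)
        if len(records) != count:
            raise ValueError(
                f"{path}: declared count {count} != stored records {len(records)}"
            )
        return PhaseSpaceSet(count=count, energy=energy, plane_mm=plane,
                             records=records.copy())


def concatenate_phase_space(sets: list[PhaseSpaceSet]) -> PhaseSpaceSet:
    """Aggregate several same-energy, same-plane sets into one.

    Records are concatenated in input order and the declared count is the
    sum of the inputs; if any input is sparse the output is sparse.
    """
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.energy != first.energy:
            raise ValueError(f"energy mismatch: {s.energy} vs {first.energy}")
        if abs(s.plane_mm - first.plane_mm) > 1e-6:
            raise ValueError(f"plane mismatch: {s.plane_mm} vs {first.plane_mm}")
    total = sum(s.count for s in sets)
    if any(s.sparse for s in sets):
        return PhaseSpaceSet(count=total, energy=first.energy, plane_mm=first.plane_mm)
    records = np.concatenate([s.records for s in sets])
    return PhaseSpaceSet(count=total, energy=first.energy,
                         plane_mm=first.plane_mm, records=records)


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------

@dataclass
class BeamSource:
    """Photon source for one energy label.

    Parametric mode samples energies from a tabulated spectrum and aims
    rays from the focal spot toward a square emission window on the
    isocenter plane.  Phase-space mode draws records cyclically and
    reshuffles on exhaustion; the number of completed passes is counted so
    latent-variance exposure is visible to the caller.
    """

    energy: str
    spectrum: tuple[tuple[float, float], ...] = ()
    plane_mm: float = DEFAULT_PLANE_MM
    window_halfsize_mm: float = 150.0
    phase_space: PhaseSpaceSet | None = None
    passes_completed: int = field(default=0, init=False)
    _cursor: int = field(default=0, init=False)
    _order: np.ndarray | None = field(default=None, init=False)

    def __post_init__(self) -> None:
        if self.phase_space is None:
            if not self.spectrum:
                raise ValueError("parametric source needs a spectrum")
            energies = np.array([e for e, _ in self.spectrum])
            probs = np.array([p for _, p in self.spectrum])
            if np.any(np.diff(energies) <= 0):
                raise ValueError("spectrum energies must be ascending")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"spectrum probabilities sum to {probs.sum()}, not 1")
        else:
            if self.phase_space.sparse:
                raise ValueError("cannot sample a sparse phase-space set")
            if self.phase_space.count == 0:
                raise ValueError("cannot sample an empty phase-space set")

    @property
    def mode(self) -> str:
        return "phase-space" if self.phase_space is not None else "parametric"

    def sample_batch(self, rng: np.random.Generator, n: int,
                     window: tuple[float, float, float, float] | None = None) -> np.ndarray:
        """Draw *n* records as a structured array (see PHSP_RECORD_DTYPE).

        ``window`` optionally restricts parametric sampling to a sub-window
        (x1, x2, y1, y2) of the emission window at the isocenter plane;
        records then carry weight area(sub)/area(full) so the expected
        fluence per unit area — and hence the calibration — is unchanged.
        """
        if self.phase_space is not None:
            return self._draw_phase_space(rng, n)
        out = np.empty(n, dtype=PHSP_RECORD_DTYPE)
        energies = np.array([e for e, _ in self.spectrum])
        probs = np.array([p for _, p in self.spectrum])
        out["E"] = rng.choice(energies, size=n, p=probs)
        h = self.window_halfsize_mm
        full_area = (2 * h) ** 2
        x1, x2, y1, y2 = -h, h, -h, h
        weight = 1.0
        if window is not None:
            x1, x2 = max(window[0], -h), min(window[1], h)
            y1, y2 = max(window[2], -h), min(window[3], h)
            if x2 <= x1 or y2 <= y1:  # sub-window misses the emission window
                x1, x2, y1, y2 = -h, h, -h, h
                weight = 0.0
            else:
                weight = (x2 - x1) * (y2 - y1) / full_area
        hx = rng.uniform(x1, x2, n)
        hy = rng.uniform(y1, y2, n)
        # focal spot at BEV (0, 0, -SAD); target on isocenter plane z=0
        dx, dy, dz = hx, hy, np.full(n, SAD_MM)
        norm = np.sqrt(dx**2 + dy**2 + dz**2)
        u, v, w = dx / norm, dy / norm, dz / norm
        t = (SAD_MM - self.plane_mm) / w  # path length focal spot -> plane
        out["x"] = u * t
        out["y"] = v * t
        out["u"], out["v"], out["w"] = u, v, w
        out["wt"] = weight
        out["type"] = PHOTON
        return out

    def _draw_phase_space(self, rng: np.random.Generator, n: int) -> np.ndarray:
        recs = self.phase_space.records
        m = len(recs)
        if self._order is None:
            self._order = np.arange(m)
        taken = []
        need = n
        while need > 0:
            avail = m - self._cursor
            k = min(avail, need)
            taken.append(recs[self._order[self._cursor: self._cursor + k]])
            self._cursor += k
            need -= k
            if self._cursor == m:
                self.passes_completed += 1
                self._order = rng.permutation(m)
                self._cursor = 0
        return np.concatenate(taken) if len(taken) > 1 else taken[0].copy()


def sample_source(source: BeamSource, rng: np.random.Generator) -> PhaseSpaceRecord:
    r = source.sample_batch(rng, 1)[0]
    return PhaseSpaceRecord(x=float(r["x"]), y=float(r["y"]), u=float(r["u"]),
                            v=float(r["v"]), w=float(r["w"]), energy=float(r["E"]),
                            weight=float(r["wt"]), ptype=int(r["type"]))


# ---------------------------------------------------------------------------
# collimation
# ---------------------------------------------------------------------------

@dataclass
class Aperture:
    """Ideal 2-D aperture at the isocenter plane (all positions in mm)."""

    jaws: tuple[float, float, float, float]  # X1, X2, Y1, Y2
    leaf_boundaries: np.ndarray  # (n_pairs + 1,) ascending y edges
    leaf_open: np.ndarray  # (2, n_pairs): bank A and bank B x positions
    transmission: float = 0.0

    def __post_init__(self) -> None:
        self.leaf_boundaries = np.asarray(self.leaf_boundaries, dtype=float)
        self.leaf_open = np.asarray(self.leaf_open, dtype=float)
        if not (0.0 <= self.transmission < 1.0):
            raise ValueError("transmission must be in [0, 1)")
        if np.any(np.diff(self.leaf_boundaries) <= 0):
            raise ValueError("leaf boundaries must be strictly ascending")
        if self.leaf_open.shape != (2, len(self.leaf_boundaries) - 1):
            raise ValueError("leaf_open must be (2, n_pairs)")

    @classmethod
    def from_control_point(cls, cp: ControlPoint, leaf_boundaries: np.ndarray,
                           transmission: float = 0.0) -> "Aperture":
        return cls(jaws=cp.jaws, leaf_boundaries=np.asarray(leaf_boundaries),
                   leaf_open=cp.mlc.copy(), transmission=transmission)

    @classmethod
    def open_field(cls, x1: float, x2: float, y1: float, y2: float,
                   transmission: float = 0.0) -> "Aperture":
        bounds = np.array([min(y1, -200.0), max(y2, 200.0)])
        leaf_open = np.array([[x1], [x2]], dtype=float)
        return cls(jaws=(x1, x2, y1, y2), leaf_boundaries=bounds,
                   leaf_open=leaf_open, transmission=transmission)

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-open-region test at the isocenter plane."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x1, x2, y1, y2 = self.jaws
        in_jaws = (x >= x1) & (x <= x2) & (y >= y1) & (y <= y2)
        pair = np.searchsorted(self.leaf_boundaries, y, side="right") - 1
        n_pairs = self.leaf_open.shape[1]
        valid = (pair >= 0) & (pair < n_pairs)
        pair_c = np.clip(pair, 0, n_pairs - 1)
        in_leaf = (x >= self.leaf_open[0, pair_c]) & (x <= self.leaf_open[1, pair_c])
        return in_jaws & valid & in_leaf

    def open_area_mm2(self) -> float:
        """Area of the open region (jaw-intersected leaf openings)."""
        x1, x2, y1, y2 = self.jaws
        lo = np.maximum(self.leaf_open[0], x1)
        hi = np.minimum(self.leaf_open[1], x2)
        widths = np.clip(hi - lo, 0.0, None)
        ylo = np.maximum(self.leaf_boundaries[:-1], y1)
        yhi = np.minimum(self.leaf_boundaries[1:], y2)
        heights = np.clip(yhi - ylo, 0.0, None)
        return float(np.sum(widths * heights))

    def open_bbox(self) -> tuple[float, float, float, float]:
        """Bounding box (x1, x2, y1, y2) of the open region, mm."""
        x1, x2, y1, y2 = self.jaws
        lo = np.maximum(self.leaf_open[0], x1)
        hi = np.minimum(self.leaf_open[1], x2)
        ylo = np.maximum(self.leaf_boundaries[:-1], y1)
        yhi = np.minimum(self.leaf_boundaries[1:], y2)
        open_pairs = (hi > lo) & (yhi > ylo)
        if not np.any(open_pairs):
            return (0.0, 0.0, 0.0, 0.0)
        return (float(lo[open_pairs].min()), float(hi[open_pairs].max()),
                float(ylo[open_pairs].min()), float(yhi[open_pairs].max()))


def collimate(record: PhaseSpaceRecord, aperture: Aperture,
              plane_mm: float = DEFAULT_PLANE_MM) -> PhaseSpaceRecord | None:
    """Project a plane record to the isocenter plane and apply the aperture.

    Returns the (possibly weight-reduced) record, or ``None`` if absorbed.
    """
    t = plane_mm / record.w
    xi = record.x + record.u * t
    yi = record.y + record.v * t
    if bool(aperture.contains(xi, yi)):
        return record
    if aperture.transmission == 0.0:
        return None
    return PhaseSpaceRecord(x=record.x, y=record.y, u=record.u, v=record.v,
                            w=record.w, energy=record.energy,
                            weight=record.weight * aperture.transmission,
                            ptype=record.ptype)


def collimate_batch(records: np.ndarray, aperture: Aperture,
                    plane_mm: float = DEFAULT_PLANE_MM) -> np.ndarray:
    """Vectorized :func:`collimate`; absorbed records are dropped."""
    t = plane_mm / records["w"]
    xi = records["x"] + records["u"] * t
    yi = records["y"] + records["v"] * t
    inside = aperture.contains(xi, yi)
    if aperture.transmission == 0.0:
        return records[inside]
    out = records.copy()
    out["wt"][~inside] *= aperture.transmission
    return out


# ---------------------------------------------------------------------------
# MU weighting and segment model
# ---------------------------------------------------------------------------

def differential_mu(plan: VMATPlan) -> list[np.ndarray]:
    """Per-segment MU for each beam: beam MU times the weight increments."""
    out = []
    for b in plan.beams:
        w = b.cum_weights
        dw = np.diff(w)
        if np.any(dw < -1e-12):
            raise ValueError(f"beam {b.name}: negative meterset increment")
        dw = np.clip(dw, 0.0, None)
        seg = b.beam_mu * dw
        # distribute any float residue so the compensated sum is exact
        residue = b.beam_mu - math.fsum(seg)
        if seg.size and residue != 0.0:
            seg[-1] += residue
        out.append(seg)
    return out


@dataclass
class Segment:
    """Midpoint discretization of the delivery between two control points."""

    gantry_deg: float
    aperture: Aperture
    mu: float
    index: int


def _mean_gantry(g1: float, g2: float) -> float:
    d = ((g2 - g1 + 180.0) % 360.0) - 180.0
    return (g1 + d / 2.0) % 360.0


def arc_segments(beam: ArcBeam, transmission: float = 0.0) -> list[Segment]:
    """Build per-segment apertures: mean gantry and linear leaf interpolation
    between the two bounding control points."""
    mus = differential_mu(VMATPlan(beams=[beam]))[0]
    segments = []
    cps = beam.control_points
    for k in range(len(cps) - 1):
        a, b = cps[k], cps[k + 1]
        jaws = tuple((np.asarray(a.jaws) + np.asarray(b.jaws)) / 2.0)
        mlc = (a.mlc + b.mlc) / 2.0
        aperture = Aperture(jaws=jaws, leaf_boundaries=beam.leaf_boundaries,
                            leaf_open=mlc, transmission=transmission)
        segments.append(Segment(gantry_deg=_mean_gantry(a.gantry_deg, b.gantry_deg),
                                aperture=aperture, mu=float(mus[k]), index=k))
    return segments


# BEV -> patient frame mapping ------------------------------------------------

def bev_to_patient(gantry_deg: float, isocenter: np.ndarray | None = None):
    """Rotation taking BEV vectors into the patient frame, plus the focal spot.

    IEC gantry convention for a head-first supine patient in DICOM
    coordinates: at gantry 0 the source is anterior (patient -y) and the
    beam travels along +y; the BEV x axis stays in the axial plane and the
    BEV y axis maps to patient +z (superior).
    """
    iso = np.zeros(3) if isocenter is None else np.asarray(isocenter, dtype=float)
    g = math.radians(gantry_deg)
    ex = np.array([math.cos(g), math.sin(g), 0.0])  # BEV +x
    ey = np.array([0.0, 0.0, 1.0])  # BEV +y -> patient superior
    ez = np.array([-math.sin(g), math.cos(g), 0.0])  # downstream
    rot = np.column_stack([ex, ey, ez])  # maps BEV (u,v,w) -> patient
    source = iso - SAD_MM * ez
    return rot, source
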