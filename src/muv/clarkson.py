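"""Sector-integration point-dose comparator with radiological depth.

Represents the single-point secondary-check algorithm class: per delivery
segment, the dose rate at the point of interest is

    reference_output * TMR(d_eff, equivalent side) * <S(r_k)>_sectors * (SAD/SPD)^2

where ``d_eff`` is the density-weighted (radiological) depth from the
source to the point, the sector radii ``r_k`` measure the aperture
boundary around the point's projection at the isocenter plane, and SPD is
the source-to-point distance.  Heterogeneities are seen *only* along the
source-point line — off-path structures change nothing, which is exactly
the blindness the Monte Carlo engine is meant to expose.

Commissioning data are plain tabulated arrays (TMR grid, circular-field
scatter factor, reference output); the packaged toy tables are generated
analytically by the fixtures module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam import SAD_MM, arc_segments, bev_to_patient
from .dicom_io import VMATPlan
from .phantom import VoxelPhantom


# ---------------------------------------------------------------------------
# commissioning tables
# ---------------------------------------------------------------------------

@dataclass
class CommissioningTables:
    """Tabulated TMR(depth, equivalent side), S(radius) and reference output."""

    energy: str
    depths_cm: np.ndarray
    sides_cm: np.ndarray
    tmr: np.ndarray  # (n_depths, n_sides)
    radii_cm: np.ndarray
    scatter: np.ndarray  # S at radii_cm
    ref_output_cgy_per_mu: float

    def __post_init__(self) -> None:
        self.depths_cm = np.asarray(self.depths_cm, dtype=float)
        self.sides_cm = np.asarray(self.sides_cm, dtype=float)
        self.tmr = np.asarray(self.tmr, dtype=float)
        self.radii_cm = np.asarray(self.radii_cm, dtype=float)
        self.scatter = np.asarray(self.scatter, dtype=float)
        if np.any(self.tmr <= 0):
            raise ValueError("TMR values must be positive")
        peak = int(np.argmax(self.tmr[:, 0]))
        if np.any(np.diff(self.tmr[peak:], axis=0) > 1e-12):
            raise ValueError("TMR must be non-increasing beyond build-up")
        if np.any(np.diff(self.scatter) < -1e-12):
            raise ValueError("S(r) must be non-decreasing")
        if self.ref_output_cgy_per_mu <= 0:
            raise ValueError("reference output must be positive")

    def tmr_at(self, depth_cm: float, side_cm: float) -> float:
        if not (self.depths_cm[0] - 1e-9 <= depth_cm <= self.depths_cm[-1] + 1e-9):
            raise ValueError(
                f"depth {depth_cm:.2f} cm outside TMR table range "
                f"[{self.depths_cm[0]}, {self.depths_cm[-1]}]"
            )
        if not (self.sides_cm[0] - 1e-9 <= side_cm <= self.sides_cm[-1] + 1e-9):
            raise ValueError(
                f"equivalent side {side_cm:.2f} cm outside TMR table range "
                f"[{self.sides_cm[0]}, {self.sides_cm[-1]}]"
            )
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((self.depths_cm, self.sides_cm), self.tmr)
        return float(interp([[np.clip(depth_cm, self.depths_cm[0], self.depths_cm[-1]),
                              np.clip(side_cm, self.sides_cm[0], self.sides_cm[-1])]])[0])

    def s_at(self, radius_cm) -> np.ndarray:
        r = np.asarray(radius_cm, dtype=float)
        if np.any(r > self.radii_cm[-1] + 1e-9):
            raise ValueError(
                f"sector radius {float(np.max(r)):.2f} cm outside S(r) table range "
                f"[0, {self.radii_cm[-1]}]"
            )
        return np.interp(np.clip(r, 0.0, self.radii_cm[-1]), self.radii_cm, self.scatter)

    def save(self, path) -> None:
        """Plain-text export: header lines then TMR and S(r) blocks."""
        with open(path, "w") as fh:
            fh.write(f"# commissioning tables\nenergy\t{self.energy}\n")
            fh.write(f"ref_output_cgy_per_mu\t{self.ref_output_cgy_per_mu:.10e}\n")
            fh.write("depths_cm\t" + "\t".join(f"{d:g}" for d in self.depths_cm) + "\n")
            fh.write("sides_cm\t" + "\t".join(f"{s:g}" for s in self.sides_cm) + "\n")
            fh.write("tmr\n")
            for row in self.tmr:
                fh.write("\t".join(f"{v:.8e}" for v in row) + "\n")
            fh.write("radii_cm\t" + "\t".join(f"{r:g}" for r in self.radii_cm) + "\n")
            fh.write("scatter\t" + "\t".join(f"{v:.8e}" for v in self.scatter) + "\n")

    @classmethod
    def load(cls, path) -> "CommissioningTables":
        lines = [ln for ln in open(path) if not ln.startswith("#")]
        fields: dict[str, list[str]] = {}
        tmr_rows: list[list[float]] = []
        in_tmr = False
        for ln in lines:
            parts = ln.rstrip("\n").split("\t")
            if parts[0] == "tmr":
                in_tmr = True
                continue
            if in_tmr and parts[0] not in ("radii_cm", "scatter"):
                tmr_rows.append([float(v) for v in parts])
                continue
            in_tmr = False
            fields[parts[0]] = parts[1:]
        return cls(energy=fields["energy"][0],
                   depths_cm=np.array([float(v) for v in fields["depths_cm"]]),
                   sides_cm=np.array([float(v) for v in fields["sides_cm"]]),
                   tmr=np.array(tmr_rows),
                   radii_cm=np.array([float(v) for v in fields["radii_cm"]]),
                   scatter=np.array([float(v) for v in fields["scatter"]]),
                   ref_output_cgy_per_mu=float(fields["ref_output_cgy_per_mu"][0]))


# ---------------------------------------------------------------------------
# radiological depth (Siddon-style exact voxel ray trace)
# ---------------------------------------------------------------------------

def radiological_depth(phantom: VoxelPhantom, source_mm, point_mm) -> float:
    """Water-equivalent depth along the source-to-point segment, cm.

    Sum over traversed voxels of geometric path length times density
    (relative to water's 1.0 g/cm^3), via exact plane-crossing traversal.
    """
    p0 = np.asarray(source_mm, dtype=float)
    p1 = np.asarray(point_mm, dtype=float)
    geom = phantom.geometry
    lo, hi = geom.bounds()
    if np.any(p1 < lo) or np.any(p1 > hi):
        raise ValueError(f"point {tuple(p1)} outside phantom extent")
    d = p1 - p0
    length = float(np.linalg.norm(d))
    if length == 0:
        return 0.0
    # entry parameter into the phantom box
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(d != 0, 1.0 / d, np.inf)
    t1 = (lo - p0) * inv
    t2 = (hi - p0) * inv
    t_in = float(np.nanmax(np.minimum(t1, t2)))
    t_in = max(t_in, 0.0)
    alphas = [np.array([t_in, 1.0])]
    for axis in range(3):
        if d[axis] == 0:
            continue
        edges = geom.edges(axis)
        a = (edges - p0[axis]) / d[axis]
        alphas.append(a[(a > t_in) & (a < 1.0)])
    t = np.unique(np.concatenate(alphas))
    t = t[(t >= t_in - 1e-12) & (t <= 1.0 + 1e-12)]
    if len(t) < 2:
        return 0.0
    mids = (t[:-1] + t[1:]) / 2.0
    seg_mm = np.diff(t) * length
    pts = p0[None, :] + mids[:, None] * d[None, :]
    idx = np.floor((pts - lo) / np.array(geom.spacing)).astype(np.int64)
    nz, ny, nx = geom.shape
    ok = ((idx[:, 0] >= 0) & (idx[:, 0] < nx) & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
          & (idx[:, 2] >= 0) & (idx[:, 2] < nz))
    idx = idx[ok]
    seg_mm = seg_mm[ok]
    rho = phantom.density[idx[:, 2], idx[:, 1], idx[:, 0]]
    return float(np.sum(seg_mm * rho) / 10.0)


# ---------------------------------------------------------------------------
# sector decomposition
# ---------------------------------------------------------------------------

@dataclass
class SectorDecomposition:
    n_sectors: int
    radii_cm: np.ndarray  # per-sector boundary distance at the isocenter plane

    def __post_init__(self) -> None:
        self.radii_cm = np.asarray(self.radii_cm, dtype=float)
        if np.any(self.radii_cm < 0):
            raise ValueError("sector radii must be non-negative")
        if len(self.radii_cm) != self.n_sectors:
            raise ValueError("one radius per sector required")


def sector_decomposition(aperture, center_xy_mm, n_sectors: int = 36,
                         r_max_mm: float | None = None) -> SectorDecomposition:
    """Per-sector distance from the point's projection to the aperture edge.

    Uses the aperture's analytic ``boundary_radius`` when available,
    otherwise a radial march plus bisection on its ``contains`` predicate.
    Sector directions sample the sector centers.
    """
    cx, cy = float(center_xy_mm[0]), float(center_xy_mm[1])
    thetas = (np.arange(n_sectors) + 0.5) * 2.0 * np.pi / n_sectors
    if hasattr(aperture, "boundary_radius"):
        radii = np.array([aperture.boundary_radius(cx, cy, th) for th in thetas])
        return SectorDecomposition(n_sectors=n_sectors, radii_cm=radii / 10.0)
    if r_max_mm is None:
        x1, x2, y1, y2 = aperture.open_bbox()
        r_max_mm = 2.0 * max(abs(x1 - cx), abs(x2 - cx), abs(y1 - cy), abs(y2 - cy), 1.0)
    radii = np.empty(n_sectors)
    for k, th in enumerate(thetas):
        ux, uy = np.cos(th), np.sin(th)
        rs = np.arange(0.0, r_max_mm, 1.0)
        inside = aperture.contains(cx + rs * ux, cy + rs * uy)
        if not inside[0]:
            radii[k] = 0.0
            continue
        blocked = np.nonzero(~inside)[0]
        if not len(blocked):
            radii[k] = r_max_mm
            continue
        a, b = rs[blocked[0] - 1], rs[blocked[0]]
        for _ in range(40):  # bisection to sub-micron radius
            m = (a + b) / 2.0
            if bool(aperture.contains(cx + m * ux, cy + m * uy)):
                a = m
            else:
                b = m
        radii[k] = (a + b) / 2.0
    return SectorDecomposition(n_sectors=n_sectors, radii_cm=radii / 10.0)


# ---------------------------------------------------------------------------
# point dose
# ---------------------------------------------------------------------------

def clarkson_point_dose(plan: VMATPlan, phantom: VoxelPhantom, point_mm,
                        tables: CommissioningTables, n_sectors: int = 36,
                        isocenter_mm=None) -> float:
    """Single-point dose in Gy for the whole plan.

    Per segment: radiological depth at the segment's gantry angle, sector
    radii from the aperture around the point's isocenter-plane projection,
    TMR at the equivalent field side (sqrt of open area), inverse-square
    from the source-to-point distance, summed with segment MU weights.
    """
    point = np.asarray(point_mm, dtype=float)
    iso = np.zeros(3) if isocenter_mm is None else np.asarray(isocenter_mm, dtype=float)
    total_cgy = 0.0
    for beam in plan.beams:
        if beam.energy != tables.energy:
            raise ValueError(f"tables are for {tables.energy}, beam is {beam.energy}")
        for seg in arc_segments(beam):
            if seg.mu == 0.0:
                continue
            rot, source = bev_to_patient(seg.gantry_deg, isocenter=iso)
            d_eff = radiological_depth(phantom, source, point)
            spd_mm = float(np.linalg.norm(point - source))
            q = rot.T @ (point - iso)  # BEV coords; q[2] is downstream of iso
            scale = SAD_MM / (SAD_MM + q[2])
            proj = (q[0] * scale, q[1] * scale)
            sectors = sector_decomposition(seg.aperture, proj, n_sectors=n_sectors)
            mean_s = float(np.mean(tables.s_at(sectors.radii_cm)))
            area_cm2 = seg.aperture.open_area_mm2() / 100.0
            side_eq = float(np.sqrt(area_cm2))
            tmr = tables.tmr_at(d_eff, side_eq)
            invsq = (SAD_MM / spd_mm) ** 2
            total_cgy += seg.mu * tables.ref_output_cgy_per_mu * tmr * mean_s * invsq
    return total_cgy / 100.0  # cGy -> Gy
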