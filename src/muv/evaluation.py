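"""Reference-point selection and TPS-vs-secondary dose comparison.

Five reference points per evaluation: the PTV centroid plus four offsets
at a configurable magnitude (default 7.5 mm, the midpoint of the 5-10 mm
window).  Offsets go along the superior/inferior axis when the PTV is tall
enough, otherwise laterally; points falling outside the PTV are pulled
inward along their axis and flagged.

Percent difference convention: 100 * (secondary - TPS) / TPS, flagged when
strictly exceeding the action limit (default 5%).  Quartiles use the
inclusive linear-interpolation rule (numpy's default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dicom_io import ROI, TPSDose
from .geometry import Geometry, trilinear
from .transport import DoseResult


@dataclass(frozen=True)
class EvalConfig:
    action_limit_percent: float = 5.0
    offset_mm: float = 7.5
    # margin (mm) the PTV must clear beyond the offset for the sup/inf axis rule
    axis_margin_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.action_limit_percent <= 0:
            raise ValueError("action limit must be positive")
        if not (5.0 <= self.offset_mm <= 10.0):
            raise ValueError("offset magnitude must lie in [5, 10] mm")


@dataclass
class ReferencePointSet:
    points_mm: np.ndarray  # (5, 3) xyz
    offset_mm: float
    offset_axes: tuple[str, str]
    pulled_inward: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if self.points_mm.shape != (5, 3):
            raise ValueError("exactly 5 reference points required")


def _inside_mask(roi: ROI, pts: np.ndarray) -> np.ndarray:
    idx = roi.geometry.voxel_of(pts)
    nz, ny, nx = roi.geometry.shape
    ok = ((idx[:, 0] >= 0) & (idx[:, 0] < nx) & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
          & (idx[:, 2] >= 0) & (idx[:, 2] < nz))
    out = np.zeros(len(pts), dtype=bool)
    sel = idx[ok]
    out[ok] = roi.mask[sel[:, 2], sel[:, 1], sel[:, 0]]
    return out


def select_reference_points(ptv: ROI, config: EvalConfig | None = None) -> ReferencePointSet:
    """PTV centroid plus four axis offsets, pulled inside the mask if needed."""
    config = config or EvalConfig()
    if not np.any(ptv.mask):
        raise ValueError("PTV mask is empty")
    geom = ptv.geometry
    iz, iy, ix = np.nonzero(ptv.mask)
    centers = np.column_stack([geom.origin[0] + ix * geom.spacing[0],
                               geom.origin[1] + iy * geom.spacing[1],
                               geom.origin[2] + iz * geom.spacing[2]])
    centroid = centers.mean(axis=0)
    z_extent = centers[:, 2].max() - centers[:, 2].min()
    mag = config.offset_mm
    if z_extent >= 2.0 * (mag + config.axis_margin_mm):
        axes = ("z", "x")
    else:
        axes = ("x", "y")
    unit = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
            "z": np.array([0, 0, 1.0])}
    offsets = [unit[axes[0]] * mag, -unit[axes[0]] * mag,
               unit[axes[1]] * mag, -unit[axes[1]] * mag]
    pts = [centroid] + [centroid + o for o in offsets]
    pulled: list[int] = []
    for k in range(1, 5):
        if _inside_mask(ptv, pts[k][None, :])[0]:
            continue
        # pull inward along the offset axis: deepest interior voxel center
        axis_vec = offsets[k - 1] / mag
        ts = np.arange(mag, -1e-9, -geom.spacing[int(np.argmax(np.abs(axis_vec)))] / 2.0)
        candidates = centroid[None, :] + ts[:, None] * axis_vec[None, :]
        inside = _inside_mask(ptv, candidates)
        if not np.any(inside):
            raise ValueError("PTV too small to host the offset reference points")
        pts[k] = candidates[np.nonzero(inside)[0][0]]
        pulled.append(k)
    pts_arr = np.array(pts)
    vox = geom.voxel_of(pts_arr)
    if len({tuple(v) for v in vox}) < 5:
        raise ValueError("PTV too small: reference points collapse onto shared voxels")
    if not np.all(_inside_mask(ptv, pts_arr)):
        raise ValueError("reference point selection failed to stay inside the PTV")
    return ReferencePointSet(points_mm=pts_arr, offset_mm=mag, offset_axes=axes,
                             pulled_inward=pulled)


def point_dose(dose, point_mm) -> float:
    """Trilinear dose lookup at a physical point.

    Accepts a :class:`TPSDose`, :class:`DoseResult`, or ``(array, Geometry)``.
    """
    if isinstance(dose, (TPSDose, DoseResult)):
        arr, geom = dose.dose, dose.geometry
    else:
        arr, geom = dose
        if not isinstance(geom, Geometry):
            raise TypeError("expected (array, Geometry) pair")
    return float(trilinear(np.asarray(arr, dtype=float), geom, np.asarray(point_mm, dtype=float)))


@dataclass
class PointComparison:
    point_mm: tuple[float, float, float]
    d_tps_gy: float
    d_secondary_gy: float
    percent_diff: float
    exceeds_limit: bool
    valid: bool = True


@dataclass
class EvalReport:
    points: list[PointComparison]
    action_limit_percent: float
    meta: dict = field(default_factory=dict)

    @property
    def diffs(self) -> np.ndarray:
        return np.array([p.percent_diff for p in self.points if p.valid])

    @property
    def n_valid(self) -> int:
        return int(sum(p.valid for p in self.points))

    @property
    def n_exceeding(self) -> int:
        return int(sum(p.exceeds_limit for p in self.points if p.valid))

    @property
    def fraction_exceeding(self) -> float:
        return self.n_exceeding / self.n_valid if self.n_valid else 0.0

    def summary(self) -> dict:
        d = self.diffs
        if not len(d):
            return {"n": 0}
        q1, q2, q3 = np.percentile(d, [25, 50, 75])  # inclusive linear rule
        return {
            "n": int(len(d)),
            "mean": float(np.mean(d)),
            "mean_abs": float(np.mean(np.abs(d))),
            "std": float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
            "q1": float(q1), "median": float(q2), "q3": float(q3),
            "n_exceeding": self.n_exceeding,
            "fraction_exceeding": self.fraction_exceeding,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "x_mm": p.point_mm[0], "y_mm": p.point_mm[1], "z_mm": p.point_mm[2],
            "d_tps_gy": p.d_tps_gy, "d_secondary_gy": p.d_secondary_gy,
            "percent_diff": p.percent_diff, "exceeds_limit": p.exceeds_limit,
            "valid": p.valid,
        } for p in self.points]
        df = pd.DataFrame(rows)
        for k, v in self.meta.items():
            df[k] = v
        return df


def compare(tps: TPSDose, secondary, points, config: EvalConfig | None = None,
            meta: dict | None = None) -> EvalReport:
    """Evaluate percent differences at the reference points.

    *secondary* may be a dose grid (``TPSDose``/``DoseResult``/pair) or a
    sequence of point doses in Gy.  Points where the TPS dose is zero are
    flagged invalid and excluded from summaries.
    """
    config = config or EvalConfig()
    pts = points.points_mm if isinstance(points, ReferencePointSet) else np.atleast_2d(points)
    is_grid = (isinstance(secondary, (TPSDose, DoseResult))
               or (isinstance(secondary, tuple) and len(secondary) == 2
                   and isinstance(secondary[1], Geometry)))
    if is_grid:
        sec_vals = np.array([point_dose(secondary, p) for p in pts])
    else:
        sec_vals = np.asarray(secondary, dtype=float)
        if sec_vals.ndim != 1 or len(sec_vals) != len(pts):
            raise ValueError("one secondary dose per point required")
    comparisons = []
    for p, d_sec in zip(pts, sec_vals):
        d_tps = point_dose(tps, p)
        if d_tps == 0.0:
            warnings.warn(f"TPS dose is zero at {tuple(p)}; point excluded", stacklevel=2)
            comparisons.append(PointComparison(tuple(p), d_tps, float(d_sec),
                                               np.nan, False, valid=False))
            continue
        diff = 100.0 * (d_sec - d_tps) / d_tps
        # strict inequality at the limit, with a float guard so an exact
        # boundary value (e.g. 2.10 vs 2.00 Gy) does not flag
        limit = config.action_limit_percent
        exceeds = abs(diff) > limit * (1.0 + 1e-9)
        comparisons.append(PointComparison(
            tuple(p), float(d_tps), float(d_sec), float(diff), bool(exceeds)))
    return EvalReport(points=comparisons,
                      action_limit_percent=config.action_limit_percent,
                      meta=meta or {})


def study_summary(reports: list[EvalReport]) -> dict:
    """Pool per-arc reports into study-level counts and statistics."""
    if not reports:
        raise ValueError("no reports to summarize")
    all_diffs = np.concatenate([r.diffs for r in reports]) if reports else np.array([])
    n_points = int(sum(r.n_valid for r in reports))
    n_exceeding = int(sum(r.n_exceeding for r in reports))
    out = {
        "n_arcs": len(reports),
        "n_points": n_points,
        "n_exceeding": n_exceeding,
        "fraction_exceeding": n_exceeding / n_points if n_points else 0.0,
        "mean_abs": float(np.mean(np.abs(all_diffs))) if len(all_diffs) else 0.0,
    }
    for key in ("site", "method"):
        groups: dict[str, list[EvalReport]] = {}
        for r in reports:
            if key in r.meta:
                groups.setdefault(str(r.meta[key]), []).append(r)
        if groups:
            out[f"by_{key}"] = {
                name: {
                    "n_points": sum(r.n_valid for r in rs),
                    "n_exceeding": sum(r.n_exceeding for r in rs),
                    "mean_abs": float(np.mean(np.abs(np.concatenate([r.diffs for r in rs])))),
                }
                for name, rs in groups.items()
            }
    return out
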