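"""Rectilinear grid geometry shared by CT, phantom and dose objects.

Conventions: patient coordinates in millimetres; arrays are indexed
``[iz, iy, ix]``; a voxel value refers to the voxel *center*; voxel
indices are 0-based.  Only axis-aligned orientations (identity direction
cosines) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IDENTITY_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


@dataclass(frozen=True)
class Geometry:
    """Axis-aligned rectilinear grid in patient space (mm)."""

    origin: tuple[float, float, float]  # center of voxel (ix=0, iy=0, iz=0), mm
    spacing: tuple[float, float, float]  # (dx, dy, dz), mm
    shape: tuple[int, int, int]  # (nz, ny, nx)
    orientation: tuple[float, ...] = field(default=IDENTITY_ORIENTATION)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        if tuple(np.round(self.orientation, 9)) != IDENTITY_ORIENTATION:
            raise ValueError("only axis-aligned (identity) orientation is supported")

    # -- extents -------------------------------------------------------------
    @property
    def nvoxels(self) -> int:
        nz, ny, nx = self.shape
        return nz * ny * nx

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along *axis* (0=x, 1=y, 2=z), mm."""
        n = self.shape[2 - axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the voxel *edges*, mm, as xyz arrays."""
        lo = np.array(self.origin) - 0.5 * np.array(self.spacing)
        n = np.array([self.shape[2], self.shape[1], self.shape[0]], dtype=float)
        hi = lo + n * np.array(self.spacing)
        return lo, hi

    def edges(self, axis: int) -> np.ndarray:
        """Voxel edge coordinates along *axis*, length n+1, mm."""
        c = self.axis_centers(axis)
        d = self.spacing[axis]
        return np.concatenate([[c[0] - d / 2], c + d / 2])

    def contains_points(self, pts: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds()
        p = np.atleast_2d(pts)
        return np.all((p >= lo) & (p <= hi), axis=1)

    # -- transforms ----------------------------------------------------------
    def point_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices (ix, iy, iz) for xyz points."""
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        return (p - np.array(self.origin)) / np.array(self.spacing)

    def index_to_point(self, idx: np.ndarray) -> np.ndarray:
        i = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.array(self.origin) + i * np.array(self.spacing)

    def voxel_of(self, pts: np.ndarray) -> np.ndarray:
        """Integer (ix, iy, iz) of the voxel containing each point (nearest center cell)."""
        return np.floor(self.point_to_index(pts) + 0.5).astype(np.int64)

    def approx_equal(self, other: "Geometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


def trilinear(values: np.ndarray, geom: Geometry, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a ``[iz, iy, ix]`` array at xyz points (mm).

    Points must lie within the voxel-center hull (edge clamping is not
    applied); outside points raise ``ValueError``.
    """
    p = np.atleast_2d(np.asarray(pts, dtype=float))
    frac = geom.point_to_index(p)  # (n, 3) as ix, iy, iz
    nz, ny, nx = geom.shape
    limits = np.array([nx - 1, ny - 1, nz - 1], dtype=float)
    if np.any(frac < -1e-9) or np.any(frac > limits + 1e-9):
        bad = p[np.any((frac < -1e-9) | (frac > limits + 1e-9), axis=1)][0]
        raise ValueError(f"point {tuple(bad)} outside interpolation domain")
    frac = np.clip(frac, 0.0, limits)
    i0 = np.floor(frac).astype(np.int64)
    i0 = np.minimum(i0, (limits - 1).astype(np.int64).clip(min=0))
    t = frac - i0
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
    ix1 = np.minimum(ix + 1, nx - 1)
    iy1 = np.minimum(iy + 1, ny - 1)
    iz1 = np.minimum(iz + 1, nz - 1)
    v = values
    out = (
        v[iz, iy, ix] * (1 - tx) * (1 - ty) * (1 - tz)
        + v[iz, iy, ix1] * tx * (1 - ty) * (1 - tz)
        + v[iz, iy1, ix] * (1 - tx) * ty * (1 - tz)
        + v[iz, iy1, ix1] * tx * ty * (1 - tz)
        + v[iz1, iy, ix] * (1 - tx) * (1 - ty) * tz
        + v[iz1, iy, ix1] * tx * (1 - ty) * tz
        + v[iz1, iy1, ix] * (1 - tx) * ty * tz
        + v[iz1, iy1, ix1] * tx * ty * tz
    )
    return out if np.asarray(pts).ndim > 1 else out[0]
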