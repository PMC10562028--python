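"""HU-to-material voxel phantom generation.

A CT volume is converted into a four-material phantom (air, lung, tissue,
bone).  Each material owns a contiguous HU interval mapped linearly onto a
mass-density interval; the interval table is continuous at the interior
boundaries, so density is a continuous, monotone function of HU.

Interval endpoint convention: rows are half-open ``[HU_min, HU_max)`` with
the final row closed; out-of-range HU clamps to the extreme row's extreme
density.  HU is resampled to the target grid *before* mapping, because the
material index is categorical and must not be averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dicom_io import CTVolume
from .geometry import Geometry

MATERIAL_NAMES = ("Air", "Lung", "Tissue", "Bone")

DEFAULT_ROWS = (
    ("Air", -1050.0, -950.0, 0.001, 0.044),
    ("Lung", -950.0, -700.0, 0.044, 0.302),
    ("Tissue", -700.0, 125.0, 0.302, 1.101),
    ("Bone", 125.0, 2000.0, 1.101, 2.088),
)


@dataclass(frozen=True)
class HUMaterialTable:
    """Ordered (material, HU interval, density interval) rows."""

    rows: tuple[tuple[str, float, float, float, float], ...] = DEFAULT_ROWS

    def __post_init__(self) -> None:
        for name, lo, hi, dlo, dhi in self.rows:
            if hi <= lo:
                raise ValueError(f"{name}: empty HU interval [{lo}, {hi}]")
            if dlo <= 0 or dhi <= 0:
                raise ValueError(f"{name}: densities must be strictly positive")
        for k in range(len(self.rows) - 1):
            if self.rows[k][2] != self.rows[k + 1][1]:
                raise ValueError("HU intervals must be contiguous and ordered")
            if self.rows[k][4] != self.rows[k + 1][3]:
                raise ValueError("density must be continuous at interior HU boundaries")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.rows)

    @property
    def hu_edges(self) -> np.ndarray:
        return np.array([self.rows[0][1]] + [r[2] for r in self.rows])


@dataclass
class VoxelPhantom:
    """Material index + mass density on a rectilinear grid.

    ``material`` indexes rows of the generating table; ``density`` is in
    g/cm^3.  An optional uniform density override (used for the water
    reference phantom) replaces the table densities but keeps material
    indices.
    """

    material: np.ndarray  # (nz, ny, nx) small ints
    density: np.ndarray  # (nz, ny, nx) g/cm^3
    geometry: Geometry
    table: HUMaterialTable = field(default_factory=HUMaterialTable)

    def __post_init__(self) -> None:
        self.material = np.asarray(self.material, dtype=np.int8)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.material.shape != self.geometry.shape or self.density.shape != self.geometry.shape:
            raise ValueError("material/density shapes must match geometry")
        if np.any(self.density <= 0):
            raise ValueError("densities must be strictly positive")

    def max_density_per_material(self) -> np.ndarray:
        out = np.zeros(len(self.table.rows))
        for m in range(len(self.table.rows)):
            sel = self.material == m
            if np.any(sel):
                out[m] = self.density[sel].max()
        return out


def map_hu(hu, table: HUMaterialTable | None = None):
    """Map HU value(s) to (material index, density g/cm^3).

    Density interpolates linearly within each row's interval; HU outside
    the table's global range clamps to the extreme row's extreme density.
    Vectorized over array input.
    """
    table = table or HUMaterialTable()
    hu_arr = np.asarray(hu, dtype=float)
    edges = table.hu_edges
    material = np.searchsorted(edges, hu_arr, side="right") - 1
    material = np.clip(material, 0, len(table.rows) - 1).astype(np.int8)
    lo = np.array([r[1] for r in table.rows])[material]
    hi = np.array([r[2] for r in table.rows])[material]
    dlo = np.array([r[3] for r in table.rows])[material]
    dhi = np.array([r[4] for r in table.rows])[material]
    frac = np.clip((hu_arr - lo) / (hi - lo), 0.0, 1.0)
    density = dlo + frac * (dhi - dlo)
    if np.isscalar(hu) or np.ndim(hu) == 0:
        return int(material), float(density)
    return material, density


def build_phantom(ct: CTVolume, table: HUMaterialTable | None = None,
                  grid: tuple[float, float, float] | float | None = None) -> VoxelPhantom:
    """Resample HU to the target grid spacing, then map to material/density.

    The target grid shares the CT origin and is cropped to lie within the
    CT extent; a grid extending past the CT volume is an error.
    """
    table = table or HUMaterialTable()
    if grid is None:
        geom = ct.geometry
        hu = np.asarray(ct.hu, dtype=float)
    else:
        if np.isscalar(grid):
            grid = (float(grid),) * 3
        cg = ct.geometry
        lo, hi = cg.bounds()
        spacing = np.asarray(grid, dtype=float)
        extent = hi - lo
        n = np.floor(extent / spacing + 1e-9).astype(int)
        if np.any(n < 1):
            raise ValueError(
                f"target spacing {tuple(spacing)} larger than CT extent {tuple(extent)}"
            )
        origin = lo + spacing / 2
        geom = Geometry(origin=tuple(origin), spacing=tuple(spacing),
                        shape=(int(n[2]), int(n[1]), int(n[0])))
        glo, ghi = geom.bounds()
        if np.any(glo < lo - 1e-6) or np.any(ghi > hi + 1e-6):
            raise ValueError(
                f"phantom grid {tuple(glo)}..{tuple(ghi)} exceeds CT extent {tuple(lo)}..{tuple(hi)}"
            )
        hu = _resample_trilinear(np.asarray(ct.hu, dtype=float), cg, geom)
    material, density = map_hu(hu, table)
    return VoxelPhantom(material=material, density=density, geometry=geom, table=table)


def _resample_trilinear(values: np.ndarray, src: Geometry, dst: Geometry) -> np.ndarray:
    from scipy.ndimage import map_coordinates

    xs = dst.axis_centers(0)
    ys = dst.axis_centers(1)
    zs = dst.axis_centers(2)
    fx = (xs - src.origin[0]) / src.spacing[0]
    fy = (ys - src.origin[1]) / src.spacing[1]
    fz = (zs - src.origin[2]) / src.spacing[2]
    gz, gy, gx = np.meshgrid(fz, fy, fx, indexing="ij")
    coords = np.stack([gz.ravel(), gy.ravel(), gx.ravel()])
    out = map_coordinates(values, coords, order=1, mode="nearest")
    return out.reshape(dst.shape)


def water_phantom(side_mm: float = 400.0, spacing_mm: float = 5.0,
                  origin: tuple[float, float, float] | None = None) -> VoxelPhantom:
    """Uniform water block: Tissue material with density overridden to 1.000."""
    n = int(round(side_mm / spacing_mm))
    if origin is None:
        origin = (-side_mm / 2 + spacing_mm / 2, spacing_mm / 2, -side_mm / 2 + spacing_mm / 2)
    geom = Geometry(origin=origin, spacing=(spacing_mm,) * 3, shape=(n, n, n))
    table = HUMaterialTable()
    tissue = table.names.index("Tissue")
    return VoxelPhantom(material=np.full(geom.shape, tissue, dtype=np.int8),
                        density=np.ones(geom.shape), geometry=geom, table=table)


def export_egsphant(phantom: VoxelPhantom, path) -> None:
    """Write the phantom in an egsphant-style text layout (cm boundaries)."""
    g = phantom.geometry
    nz, ny, nx = g.shape
    with open(path, "w") as fh:
        fh.write(f"{len(phantom.table.rows)}\n")
        for name in phantom.table.names:
            fh.write(f"{name}\n")
        fh.write("  " + "  ".join("0.0" for _ in phantom.table.rows) + "\n")
        fh.write(f"{nx} {ny} {nz}\n")
        for axis in (0, 1, 2):
            fh.write(" ".join(f"{v / 10.0:.4f}" for v in phantom.geometry.edges(axis)) + "\n")
        for iz in range(nz):
            for iy in range(ny):
                fh.write("".join(str(int(m) + 1) for m in phantom.material[iz, iy]) + "\n")
            fh.write("\n")
        for iz in range(nz):
            for iy in range(ny):
                fh.write(" ".join(f"{d:.6f}" for d in phantom.density[iz, iy]) + "\n")
            fh.write("\n")
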