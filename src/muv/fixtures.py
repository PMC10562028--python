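"""Synthetic inputs for the whole pipeline.

Generates CT series, structure sets, toy VMAT plans, TPS-like dose grids,
phase-space files and commissioning tables so the full workflow is
exercisable without any external data.  All generators are deterministic
under a fixed seed (byte-identical files, including UIDs).

The "mc-proxy" TPS dose mode runs the package's own engine at high
histories and relabels the output as TPS truth, optionally perturbed by a
stated multiplicative field; this circularity is deliberate — it is the
evaluation logic, not TPS fidelity, that the fixtures support testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _dicom
from .beam import DEFAULT_PLANE_MM, PHSP_RECORD_DTYPE, PhaseSpaceSet, write_phase_space
from .calibration import (
    DEFAULT_REFERENCE_OUTPUT_CGY_PER_MU,
    DEFAULT_SPECTRA,
    CalibrationFactor,
    reference_setup,
)
from .clarkson import CommissioningTables, clarkson_point_dose
from .dicom_io import (
    CT_SOP_CLASS,
    RTPLAN_SOP_CLASS,
    RTSTRUCT_SOP_CLASS,
    ArcBeam,
    ControlPoint,
    CTVolume,
    ROI,
    StructureSet,
    TPSDose,
    VMATPlan,
)
from .geometry import Geometry
from .phantom import VoxelPhantom
from .transport import simulate_arc


def _uid(seed: int, k: int) -> str:
    return f"{_dicom.UID_ROOT}.{seed % 10**8}.{k}"


# ---------------------------------------------------------------------------
# CT volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    shape: str  # slab | sphere | cylinder
    hu: float
    # slab: axis + (lo, hi) mm; sphere: center + radius; cylinder: axis +
    # center (in-plane) + radius (+ optional extent along axis)
    axis: str = "z"
    lo: float = 0.0
    hi: float = 0.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 0.0
    extent: tuple[float, float] | None = None


@dataclass(frozen=True)
class PhantomRecipe:
    extent_mm: tuple[float, float, float] = (200.0, 200.0, 200.0)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_hu: float = 0.0
    regions: tuple[Region, ...] = ()
    noise_sigma_hu: float = 0.0
    origin_mm: tuple[float, float, float] | None = None


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def make_ct(recipe: PhantomRecipe, seed: int = 0) -> CTVolume:
    """Render a recipe into a CT volume (deterministic given seed)."""
    ext = np.asarray(recipe.extent_mm, dtype=float)
    sp = np.asarray(recipe.spacing_mm, dtype=float)
    n = np.maximum(np.rint(ext / sp).astype(int), 1)  # (nx, ny, nz)
    origin = (np.asarray(recipe.origin_mm, dtype=float) if recipe.origin_mm is not None
              else -ext / 2 + sp / 2)
    geom = Geometry(origin=tuple(origin), spacing=tuple(sp),
                    shape=(int(n[2]), int(n[1]), int(n[0])))
    xs, ys, zs = (geom.axis_centers(a) for a in range(3))
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    hu = np.full(geom.shape, float(recipe.background_hu))
    coords = {"x": gx, "y": gy, "z": gz}
    for r in recipe.regions:
        if r.shape == "slab":
            c = coords[r.axis]
            sel = (c >= r.lo) & (c <= r.hi)
        elif r.shape == "sphere":
            cx, cy, cz = r.center
            sel = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= r.radius**2
        elif r.shape == "cylinder":
            others = [a for a in "xyz" if a != r.axis]
            c0 = r.center[_AXIS_INDEX[others[0]]]
            c1 = r.center[_AXIS_INDEX[others[1]]]
            sel = ((coords[others[0]] - c0) ** 2 + (coords[others[1]] - c1) ** 2
                   <= r.radius**2)
            if r.extent is not None:
                sel &= (coords[r.axis] >= r.extent[0]) & (coords[r.axis] <= r.extent[1])
        else:
            raise ValueError(f"unknown region shape {r.shape!r}")
        hu[sel] = r.hu
    if recipe.noise_sigma_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + np.rint(rng.normal(0.0, recipe.noise_sigma_hu, geom.shape))
    return CTVolume(hu=np.rint(hu).astype(np.int16), geometry=geom)


def write_ct_series(ct: CTVolume, out_dir, seed: int = 0) -> list[Path]:
    """Write a CT volume as a valid slice series (intercept -1024, slope 1)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nz, ny, nx = ct.geometry.shape
    study, series, frame = _uid(seed, 1), _uid(seed, 2), _uid(seed, 3)
    files = []
    for iz in range(nz):
        stored = (np.asarray(ct.hu[iz], dtype=np.int32) + 1024).astype("<i2")
        ds = _dicom.Dataset(
            SOPClassUID=CT_SOP_CLASS,
            SOPInstanceUID=_uid(seed, 100 + iz),
            StudyInstanceUID=study,
            SeriesInstanceUID=series,
            FrameOfReferenceUID=frame,
            Modality="CT",
            PatientName="FIXTURE^CASE",
            PatientID="FIXTURE",
            InstanceNumber=iz + 1,
            ImagePositionPatient=[ct.geometry.origin[0], ct.geometry.origin[1],
                                  ct.geometry.origin[2] + iz * ct.geometry.spacing[2]],
            ImageOrientationPatient=[1, 0, 0, 0, 1, 0],
            PixelSpacing=[ct.geometry.spacing[1], ct.geometry.spacing[0]],
            SliceThickness=ct.geometry.spacing[2],
            Rows=ny,
            Columns=nx,
            SamplesPerPixel=1,
            PhotometricInterpretation="MONOCHROME2",
            BitsAllocated=16,
            BitsStored=16,
            HighBit=15,
            PixelRepresentation=1,
            RescaleIntercept=-1024.0,
            RescaleSlope=1.0,
            PixelData=stored.tobytes(),
        )
        f = out_dir / f"ct_{iz:03d}.dcm"
        _dicom.write_file(f, ds)
        files.append(f)
    return files


# canned recipes -------------------------------------------------------------

def water_cube_recipe(side_mm: float = 200.0, spacing_mm: float = 2.0) -> PhantomRecipe:
    return PhantomRecipe(extent_mm=(side_mm,) * 3, spacing_mm=(spacing_mm,) * 3,
                         background_hu=0.0)


def thorax_recipe(spacing_mm: float = 2.5) -> PhantomRecipe:
    """Tissue shell, two lung cylinders (HU -750), bone rod (HU 700), in air."""
    return PhantomRecipe(
        extent_mm=(300.0, 220.0, 160.0), spacing_mm=(spacing_mm,) * 3,
        background_hu=-1000.0,
        regions=(
            Region(shape="cylinder", axis="z", hu=0.0, center=(0, 0, 0), radius=100.0),
            Region(shape="cylinder", axis="z", hu=-750.0, center=(-55, 0, 0), radius=38.0),
            Region(shape="cylinder", axis="z", hu=-750.0, center=(55, 0, 0), radius=38.0),
            Region(shape="cylinder", axis="z", hu=700.0, center=(0, 55, 0), radius=12.0),
        ),
    )


def lateral_slab_recipe(slab_hu: float, side_mm: float = 220.0,
                        spacing_mm: float = 2.5,
                        slab_x: tuple[float, float] = (35.0, 95.0)) -> PhantomRecipe:
    """Water cube with a lateral slab (lung or water HU) beside the beam path."""
    return PhantomRecipe(
        extent_mm=(side_mm,) * 3, spacing_mm=(spacing_mm,) * 3, background_hu=0.0,
        regions=(Region(shape="slab", axis="x", hu=slab_hu,
                        lo=slab_x[0], hi=slab_x[1]),),
    )


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlanRecipe:
    site: str = "generic"
    energy: str = "6X"
    n_arcs: int = 1
    control_points: int | tuple[int, ...] = 98
    beam_mu: float = 200.0
    gantry_start: float = 181.0
    gantry_span: float = 358.0  # degrees swept by each arc
    aperture: str = "square"  # square | conformal_sphere
    field_halfsize_mm: float = 50.0
    target_radius_mm: float = 25.0
    modulate: bool = False  # sinusoidal aperture-size modulation along the arc
    n_leaf_pairs: int = 20
    leaf_span_mm: float = 100.0  # leaves cover +-span in y
    dose_grid_mm: float = 2.0


def _aperture_at(recipe: PlanRecipe, boundaries: np.ndarray, frac: float):
    """(jaws, mlc) for the fractional arc position ``frac`` in [0, 1]."""
    scale = 1.0 + (0.2 * np.sin(2.0 * np.pi * frac) if recipe.modulate else 0.0)
    centers = (boundaries[:-1] + boundaries[1:]) / 2.0
    if recipe.aperture == "square":
        h = recipe.field_halfsize_mm * scale
        open_pairs = np.abs(centers) <= h + 1e-9
        mlc = np.where(open_pairs, -h, 0.0), np.where(open_pairs, h, 0.0)
        jaws = (-h, h, -h, h)
    elif recipe.aperture == "conformal_sphere":
        r = recipe.target_radius_mm * scale
        # nearest |y| inside each leaf pair
        near = np.where((boundaries[:-1] <= 0) & (boundaries[1:] >= 0), 0.0,
                        np.minimum(np.abs(boundaries[:-1]), np.abs(boundaries[1:])))
        half = np.sqrt(np.clip(r**2 - near**2, 0.0, None))
        mlc = -half, half
        jaws = (-r, r, -r, r)
    else:
        raise ValueError(f"unknown aperture program {recipe.aperture!r}")
    return jaws, np.vstack(mlc)


def make_plan(recipe: PlanRecipe) -> VMATPlan:
    """Build an in-memory plan; cumulative weights are uniform."""
    boundaries = np.linspace(-recipe.leaf_span_mm, recipe.leaf_span_mm,
                             recipe.n_leaf_pairs + 1)
    cps_per_arc = (recipe.control_points if isinstance(recipe.control_points, tuple)
                   else (recipe.control_points,) * recipe.n_arcs)
    if len(cps_per_arc) != recipe.n_arcs:
        raise ValueError("one control-point count per arc required")
    beams = []
    for a in range(recipe.n_arcs):
        ncp = cps_per_arc[a]
        if ncp < 2:
            raise ValueError("arcs need at least 2 control points")
        weights = np.linspace(0.0, 1.0, ncp)
        direction = 1 if a % 2 == 0 else -1  # alternate CW/CCW like clinical arcs
        cps = []
        for k in range(ncp):
            frac = k / (ncp - 1)
            gantry = (recipe.gantry_start + direction * frac * recipe.gantry_span) % 360.0
            jaws, mlc = _aperture_at(recipe, boundaries, frac)
            cps.append(ControlPoint(gantry_deg=gantry, jaws=jaws, mlc=mlc,
                                    cum_weight=float(weights[k])))
        beams.append(ArcBeam(energy=recipe.energy, beam_mu=recipe.beam_mu,
                             control_points=cps, leaf_boundaries=boundaries,
                             beam_number=a + 1, name=f"{recipe.site}-arc{a + 1}",
                             is_arc=True))
    return VMATPlan(beams=beams, label=recipe.site)


def write_rtplan(plan: VMATPlan, path, seed: int = 0) -> Path:
    """Serialize a plan as an RT Plan file readable by ``read_rtplan``."""
    beam_items = []
    ref_items = []
    for b in plan.beams:
        if b.energy.endswith("FFF"):
            energy_mv = float(b.energy[:-3])
            fluence = [_dicom.Dataset(FluenceMode="NON_STANDARD", FluenceModeID="FFF")]
        else:
            energy_mv = float(b.energy[:-1])
            fluence = [_dicom.Dataset(FluenceMode="STANDARD")]
        cp_items = []
        for k, cp in enumerate(b.control_points):
            devs = [
                _dicom.Dataset(RTBeamLimitingDeviceType="ASYMX",
                               LeafJawPositions=[cp.jaws[0], cp.jaws[1]]),
                _dicom.Dataset(RTBeamLimitingDeviceType="ASYMY",
                               LeafJawPositions=[cp.jaws[2], cp.jaws[3]]),
                _dicom.Dataset(RTBeamLimitingDeviceType="MLCX",
                               LeafJawPositions=list(cp.mlc[0]) + list(cp.mlc[1])),
            ]
            item = _dicom.Dataset(ControlPointIndex=k,
                                  GantryAngle=cp.gantry_deg,
                                  CumulativeMetersetWeight=cp.cum_weight,
                                  BeamLimitingDevicePositionSequence=devs)
            if k == 0:
                item.NominalBeamEnergy = energy_mv
                item.BeamLimitingDeviceAngle = 0.0
                item.PatientSupportAngle = 0.0
                item.IsocenterPosition = [0.0, 0.0, 0.0]
            cp_items.append(item)
        beam_items.append(_dicom.Dataset(
            BeamNumber=b.beam_number,
            BeamName=b.name or f"beam{b.beam_number}",
            BeamType="DYNAMIC" if b.is_arc else "STATIC",
            RadiationType="PHOTON",
            TreatmentDeliveryType="TREATMENT",
            SourceAxisDistance=1000.0,
            PrimaryFluenceModeSequence=fluence,
            BeamLimitingDeviceSequence=[
                _dicom.Dataset(RTBeamLimitingDeviceType="ASYMX", NumberOfLeafJawPairs=1),
                _dicom.Dataset(RTBeamLimitingDeviceType="ASYMY", NumberOfLeafJawPairs=1),
                _dicom.Dataset(RTBeamLimitingDeviceType="MLCX",
                               NumberOfLeafJawPairs=len(b.leaf_boundaries) - 1,
                               LeafPositionBoundaries=list(b.leaf_boundaries)),
            ],
            FinalCumulativeMetersetWeight=1.0,
            NumberOfControlPoints=len(b.control_points),
            ControlPointSequence=cp_items,
        ))
        ref_items.append(_dicom.Dataset(ReferencedBeamNumber=b.beam_number,
                                        BeamMeterset=b.beam_mu))
    ds = _dicom.Dataset(
        SOPClassUID=RTPLAN_SOP_CLASS,
        SOPInstanceUID=_uid(seed, 10),
        StudyInstanceUID=_uid(seed, 1),
        SeriesInstanceUID=_uid(seed, 11),
        FrameOfReferenceUID=_uid(seed, 3),
        Modality="RTPLAN",
        PatientName="FIXTURE^CASE",
        PatientID="FIXTURE",
        RTPlanLabel=plan.label,
        RTPlanGeometry="PATIENT",
        FractionGroupSequence=[_dicom.Dataset(FractionGroupNumber=1,
                                              NumberOfFractionsPlanned=1,
                                              NumberOfBeams=len(plan.beams),
                                              ReferencedBeamSequence=ref_items)],
        BeamSequence=beam_items,
    )
    _dicom.write_file(path, ds)
    return Path(path)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def sphere_roi(ct: CTVolume, center_mm, radius_mm: float, name: str = "PTV") -> ROI:
    geom = ct.geometry
    xs, ys, zs = (geom.axis_centers(a) for a in range(3))
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    cx, cy, cz = center_mm
    mask = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2 <= radius_mm**2
    return ROI(name=name, mask=mask, geometry=geom)


def write_rtstruct(path, ct: CTVolume, spheres: list[tuple[str, tuple, float]],
                   seed: int = 0, n_vertices: int = 90) -> Path:
    """Write sphere structures as per-slice circular contours."""
    geom = ct.geometry
    zs = geom.axis_centers(2)
    roi_items, contour_items = [], []
    for num, (name, center, radius) in enumerate(spheres, start=1):
        roi_items.append(_dicom.Dataset(ROINumber=num, ROIName=name,
                                        ReferencedFrameOfReferenceUID=_uid(seed, 3)))
        contours = []
        cx, cy, cz = center
        for z in zs:
            h2 = radius**2 - (z - cz) ** 2
            if h2 <= 0:
                continue
            r = np.sqrt(h2)
            th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
            pts = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th),
                                   np.full(n_vertices, z)])
            contours.append(_dicom.Dataset(ContourGeometricType="CLOSED_PLANAR",
                                           NumberOfContourPoints=n_vertices,
                                           ContourData=pts.ravel().tolist()))
        contour_items.append(_dicom.Dataset(ReferencedROINumber=num,
                                            ContourSequence=contours))
    ds = _dicom.Dataset(
        SOPClassUID=RTSTRUCT_SOP_CLASS,
        SOPInstanceUID=_uid(seed, 20),
        StudyInstanceUID=_uid(seed, 1),
        SeriesInstanceUID=_uid(seed, 21),
        FrameOfReferenceUID=_uid(seed, 3),
        Modality="RTSTRUCT",
        PatientName="FIXTURE^CASE",
        PatientID="FIXTURE",
        StructureSetLabel="fixture",
        StructureSetROISequence=roi_items,
        ROIContourSequence=contour_items,
    )
    _dicom.write_file(path, ds)
    return Path(path)


# ---------------------------------------------------------------------------
# TPS-like dose
# ---------------------------------------------------------------------------

def make_tps_dose(plan: VMATPlan, phantom: VoxelPhantom,
                  fcal_by_energy: dict[str, CalibrationFactor],
                  mode: str = "mc-proxy", histories: int = 200_000,
                  seed: int = 0, n_jobs: int = 4,
                  perturbation: np.ndarray | None = None,
                  source_factory=None) -> TPSDose:
    """Manufacture a TPS reference dose grid.

    ``mc-proxy`` runs the engine and relabels the calibrated result as TPS
    truth; ``perturbation`` is an optional multiplicative field on the
    phantom grid (e.g. 1.07 inside a lung ROI) to create known
    disagreement.  ``analytic`` produces an exponential broad-beam dose for
    closed-form checks (single static gantry-0 beam only).
    """
    from .calibration import apply_calibration, default_source

    if mode == "analytic":
        return _analytic_dose(plan, phantom)
    if mode != "mc-proxy":
        raise ValueError(f"unknown mode {mode!r}")
    make_source = source_factory or default_source
    total = np.zeros(phantom.geometry.shape)
    for i, beam in enumerate(plan.beams):
        result = simulate_arc(phantom, make_source(beam.energy), beam,
                              histories=histories, n_jobs=n_jobs,
                              base_seed=seed + 1000 * i)
        total += apply_calibration(result, fcal_by_energy[beam.energy],
                                   mu=beam.beam_mu, energy=beam.energy)
    if perturbation is not None:
        if perturbation.shape != total.shape:
            raise ValueError("perturbation field must match the phantom grid")
        total = total * perturbation
    return TPSDose(dose=total, geometry=phantom.geometry)


def _analytic_dose(plan: VMATPlan, phantom: VoxelPhantom,
                   mu_eff_per_cm: float = 0.05, d0_gy_per_mu: float = 0.01) -> TPSDose:
    geom = phantom.geometry
    xs, ys, zs = (geom.axis_centers(a) for a in range(3))
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    dose = np.zeros(geom.shape)
    lo, _ = geom.bounds()
    for beam in plan.beams:
        cp = beam.control_points[0]
        if any(c.gantry_deg != cp.gantry_deg for c in beam.control_points):
            raise ValueError("analytic mode supports static beams only")
        if cp.gantry_deg != 0.0:
            raise ValueError("analytic mode supports gantry 0 only")
        x1, x2, y1, y2 = cp.jaws
        infield = (gx >= x1) & (gx <= x2) & (gz >= y1) & (gz <= y2)
        depth_cm = (gy - lo[1]) / 10.0
        dose += beam.beam_mu * d0_gy_per_mu * np.exp(-mu_eff_per_cm * depth_cm) * infield
    return TPSDose(dose=dose, geometry=geom)


# ---------------------------------------------------------------------------
# phase space and commissioning tables
# ---------------------------------------------------------------------------

def make_phase_space(n: int, spectrum=None, seed: int = 0, energy: str = "6X",
                     plane_mm: float = DEFAULT_PLANE_MM, sparse: bool = False,
                     path=None) -> PhaseSpaceSet:
    """Deterministic synthetic phase-space set (optionally header-only)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if sparse:
        ps = PhaseSpaceSet(count=n, energy=energy, plane_mm=plane_mm)
    else:
        rng = np.random.default_rng(seed)
        spectrum = spectrum or DEFAULT_SPECTRA[energy]
        energies = np.array([e for e, _ in spectrum])
        probs = np.array([p for _, p in spectrum])
        recs = np.zeros(n, dtype=PHSP_RECORD_DTYPE)
        recs["E"] = rng.choice(energies, size=n, p=probs)
        recs["x"] = rng.uniform(-60.0, 60.0, n)
        recs["y"] = rng.uniform(-60.0, 60.0, n)
        tx = rng.uniform(-120.0, 120.0, n)
        ty = rng.uniform(-120.0, 120.0, n)
        d = np.column_stack([tx - recs["x"], ty - recs["y"], np.full(n, plane_mm)])
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        recs["u"], recs["v"], recs["w"] = d[:, 0], d[:, 1], d[:, 2]
        recs["wt"] = 1.0
        ps = PhaseSpaceSet(count=n, energy=energy, plane_mm=plane_mm, records=recs)
    if path is not None:
        write_phase_space(path, ps)
    return ps


_TMR_MU_EFF = {"6X": 0.046, "6FFF": 0.052, "10X": 0.038, "10FFF": 0.042}
_TMR_DMAX_CM = 1.5
_SCATTER_R0_CM = 6.0


def make_tables(energy: str = "6X", normalize: bool = True) -> CommissioningTables:
    """Analytic toy commissioning tables.

    TMR: linear build-up to 1.5 cm then exponential fall-off with a mild
    field-size factor; S(r) = 1 - exp(-r / 6 cm).  When ``normalize`` is
    set, the reference output is fixed so the comparator reproduces the toy
    TPS reference output under the calibration reference conditions.
    """
    depths = np.arange(0.0, 40.5, 0.5)
    sides = np.arange(2.0, 41.0, 1.0)
    mu = _TMR_MU_EFF[energy]
    tmr = np.empty((len(depths), len(sides)))
    for j, s in enumerate(sides):
        size_factor = 1.0 + 0.002 * (s - 10.0)
        peak = np.clip(depths / _TMR_DMAX_CM, 0.05, 1.0) ** 0.6
        fall = np.exp(-mu * np.clip(depths - _TMR_DMAX_CM, 0.0, None))
        tmr[:, j] = size_factor * peak * fall
    radii = np.arange(0.0, 30.25, 0.25)
    scatter = 1.0 - np.exp(-radii / _SCATTER_R0_CM)
    tables = CommissioningTables(energy=energy, depths_cm=depths, sides_cm=sides,
                                 tmr=tmr, radii_cm=radii, scatter=scatter,
                                 ref_output_cgy_per_mu=1.0)
    if not normalize:
        return tables
    setup = reference_setup(energy=energy, spacing_mm=10.0)
    per_mu = clarkson_point_dose(setup.plan, setup.phantom, setup.point_mm,
                                 tables) / setup.plan.beams[0].beam_mu
    target_gy_per_mu = DEFAULT_REFERENCE_OUTPUT_CGY_PER_MU[energy] * 0.01
    tables.ref_output_cgy_per_mu = target_gy_per_mu / per_mu
    return tables


# ---------------------------------------------------------------------------
# analytic apertures for sector-integration identity tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularAperture:
    """Disc of given radius; boundary radius is analytic."""

    center_mm: tuple[float, float]
    radius_mm: float
    transmission: float = 0.0

    def contains(self, x, y):
        return ((np.asarray(x) - self.center_mm[0]) ** 2
                + (np.asarray(y) - self.center_mm[1]) ** 2) <= self.radius_mm**2

    def boundary_radius(self, cx: float, cy: float, theta: float) -> float:
        # distance from (cx, cy) to the circle along direction theta
        ox = cx - self.center_mm[0]
        oy = cy - self.center_mm[1]
        ux, uy = np.cos(theta), np.sin(theta)
        b = ox * ux + oy * uy
        c = ox**2 + oy**2 - self.radius_mm**2
        disc = b**2 - c
        if c > 0 or disc < 0:
            return 0.0
        return float(-b + np.sqrt(disc))

    def open_area_mm2(self) -> float:
        return float(np.pi * self.radius_mm**2)

    def open_bbox(self):
        cx, cy = self.center_mm
        r = self.radius_mm
        return (cx - r, cx + r, cy - r, cy + r)


@dataclass(frozen=True)
class HalfDiscAperture:
    """Disc with one half blocked by an edge through the center at
    ``edge_angle``: open where the direction from the center lies in
    (edge_angle, edge_angle + pi)."""

    center_mm: tuple[float, float]
    radius_mm: float
    edge_angle_rad: float = 0.0
    transmission: float = 0.0

    def contains(self, x, y):
        dx = np.asarray(x) - self.center_mm[0]
        dy = np.asarray(y) - self.center_mm[1]
        in_disc = dx**2 + dy**2 <= self.radius_mm**2
        # open half-plane: component along the inward normal positive
        nx = -np.sin(self.edge_angle_rad)
        ny = np.cos(self.edge_angle_rad)
        return in_disc & (dx * nx + dy * ny > 0)

    def boundary_radius(self, cx: float, cy: float, theta: float) -> float:
        if cx != self.center_mm[0] or cy != self.center_mm[1]:
            raise NotImplementedError("analytic radius only at the disc center")
        phi = (theta - self.edge_angle_rad) % (2.0 * np.pi)
        return self.radius_mm if 0.0 < phi < np.pi else 0.0

    def open_area_mm2(self) -> float:
        return float(np.pi * self.radius_mm**2 / 2.0)

    def open_bbox(self):
        cx, cy = self.center_mm
        r = self.radius_mm
        return (cx - r, cx + r, cy - r, cy + r)


# ---------------------------------------------------------------------------
# study roster (plan-information table emulation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyPlanInfo:
    name: str
    site: str
    energy: str
    n_arcs: int
    control_points: tuple[int, ...]
    dose_grid_mm: float


STUDY_ROSTER: tuple[StudyPlanInfo, ...] = (
    StudyPlanInfo("Abdominal 1", "abdomen", "6FFF", 3, (114,) * 3, 1.25),
    StudyPlanInfo("Abdominal 2", "abdomen", "10FFF", 3, (114,) * 3, 1.25),
    StudyPlanInfo("Brain 1", "brain", "6FFF", 3, (98,) * 3, 1.25),
    StudyPlanInfo("Brain 2", "brain", "6X", 4, (178, 178, 98, 98), 2.0),
    StudyPlanInfo("Head & Neck 1", "head_neck", "10FFF", 3, (178,) * 3, 1.25),
    StudyPlanInfo("Head & Neck 2", "head_neck", "6FFF", 3, (178,) * 3, 1.25),
    StudyPlanInfo("Lung 1", "lung", "6FFF", 3, (114,) * 3, 1.25),
    StudyPlanInfo("Lung 2", "lung", "6FFF", 3, (114,) * 3, 1.25),
    StudyPlanInfo("Lung 3", "lung", "6FFF", 3, (98,) * 3, 1.25),
    StudyPlanInfo("Lung 4", "lung", "6FFF", 3, (114,) * 3, 1.25),
    StudyPlanInfo("Prostate 1", "prostate", "10X", 2, (178,) * 2, 2.0),
    StudyPlanInfo("Prostate 2", "prostate", "10X", 2, (178,) * 2, 2.0),
    StudyPlanInfo("Prostate 3", "prostate", "6X", 2, (178,) * 2, 2.0),
)


def make_study_fixture() -> list[tuple[StudyPlanInfo, VMATPlan]]:
    """Instantiate the 13-plan roster as toy conformal plans."""
    out = []
    for info in STUDY_ROSTER:
        recipe = PlanRecipe(site=info.site, energy=info.energy, n_arcs=info.n_arcs,
                            control_points=info.control_points,
                            aperture="conformal_sphere", target_radius_mm=25.0,
                            dose_grid_mm=info.dose_grid_mm)
        out.append((info, make_plan(recipe)))
    return out
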