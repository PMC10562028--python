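"""DICOM-RT ingestion and export.

Reads the four object types the verification workflow touches (CT Image
series, RT Plan, RT Structure Set, RT Dose) into neutral in-memory types,
writes calibrated RT Dose files, and strips identifying metadata.  All
coordinates are patient-space millimetres; HU rescaling is applied at read
time so raw stored values never escape the reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _dicom
from .geometry import Geometry, trilinear

SUPPORTED_ENERGIES = ("6X", "6FFF", "10X", "10FFF")

CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """CT volume in Hounsfield units on an axis-aligned grid."""

    hu: np.ndarray  # (nz, ny, nx) int/float HU
    geometry: Geometry

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.shape != self.geometry.shape:
            raise ValueError(f"hu shape {self.hu.shape} != geometry {self.geometry.shape}")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.geometry.origin

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.geometry.spacing


@dataclass
class ControlPoint:
    """One sampled machine state along an arc."""

    gantry_deg: float
    jaws: tuple[float, float, float, float]  # X1, X2, Y1, Y2 at isocenter plane, mm
    mlc: np.ndarray  # (2, n_pairs): bank A (left) and bank B (right) edges, mm
    cum_weight: float

    def __post_init__(self) -> None:
        self.gantry_deg = float(self.gantry_deg) % 360.0
        self.mlc = np.asarray(self.mlc, dtype=float)
        x1, x2, y1, y2 = self.jaws
        if x1 > x2 or y1 > y2:
            raise ValueError(f"invalid jaw ordering: {self.jaws}")
        if self.mlc.ndim != 2 or self.mlc.shape[0] != 2:
            raise ValueError(f"mlc must be (2, n_pairs), got {self.mlc.shape}")

    def crossed_pairs(self, tol: float = 1e-6) -> np.ndarray:
        """Indices of leaf pairs where bank A crosses bank B."""
        return np.nonzero(self.mlc[0] > self.mlc[1] + tol)[0]


@dataclass
class ArcBeam:
    """A VMAT arc: ordered control points plus beam-level metadata."""

    energy: str
    beam_mu: float
    control_points: list[ControlPoint]
    leaf_boundaries: np.ndarray  # (n_pairs + 1,) leaf-pair y edges at isocenter, mm
    beam_number: int = 1
    name: str = ""
    is_arc: bool = True
    unsupported: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.energy not in SUPPORTED_ENERGIES:
            raise ValueError(f"energy {self.energy!r} not in {SUPPORTED_ENERGIES}")
        if len(self.control_points) < 2:
            raise ValueError("an arc needs at least 2 control points")
        w = np.array([cp.cum_weight for cp in self.control_points])
        if np.any(np.diff(w) < -1e-9):
            raise ValueError("cumulative meterset weights must be non-decreasing")
        if abs(w[0]) > 1e-9 or abs(w[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative weights must run from 0 to 1")
        self.leaf_boundaries = np.asarray(self.leaf_boundaries, dtype=float)

    @property
    def cum_weights(self) -> np.ndarray:
        return np.array([cp.cum_weight for cp in self.control_points])


@dataclass
class VMATPlan:
    beams: list[ArcBeam]
    label: str = "plan"

    def __post_init__(self) -> None:
        if not self.beams:
            raise ValueError("plan has no beams")

    @property
    def n_arcs(self) -> int:
        return sum(1 for b in self.beams if b.is_arc)


@dataclass
class ROI:
    name: str
    mask: np.ndarray  # boolean, on the declared geometry
    geometry: Geometry
    contours: list[np.ndarray] = field(default_factory=list)  # each (n, 3) xyz mm


@dataclass
class StructureSet:
    rois: dict[str, ROI]

    def __getitem__(self, name: str) -> ROI:
        return self.rois[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rois


@dataclass
class TPSDose:
    """TPS reference dose grid in Gy."""

    dose: np.ndarray  # (nz, ny, nx), Gy
    geometry: Geometry

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.geometry.shape:
            raise ValueError("dose shape does not match geometry")
        if np.any(self.dose < 0) or not np.all(np.isfinite(self.dose)):
            raise ValueError("dose must be finite and non-negative")

    def at(self, pts: np.ndarray) -> np.ndarray:
        return trilinear(self.dose, self.geometry, pts)


# ---------------------------------------------------------------------------
# CT series
# ---------------------------------------------------------------------------

def read_ct_series(path) -> CTVolume:
    """Load a directory of CT slice files into a :class:`CTVolume`.

    Slices are sorted by patient-z position and the rescale slope/intercept
    is applied.  Mixed series and non-uniform slice spacing are rejected.
    """
    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = _dicom.read_file(f)
        except ValueError:
            continue
        if ds.get("Modality") == "CT":
            slices.append((f, ds))
    if not slices:
        raise ValueError(f"no CT slices found in {path}")
    series_uids = {ds.get("SeriesInstanceUID") for _, ds in slices}
    if len(series_uids) != 1:
        raise ValueError(f"mixed CT series in {path}: {sorted(map(str, series_uids))}")
    for tag in ("ImagePositionPatient", "PixelSpacing", "Rows", "Columns"):
        for f, ds in slices:
            if tag not in ds:
                raise ValueError(f"{f.name}: missing required geometry tag {tag}")
    slices.sort(key=lambda fd: fd[1].ImagePositionPatient[2])
    zs = np.array([ds.ImagePositionPatient[2] for _, ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise ValueError("duplicate or non-monotone slice positions")
        if not np.allclose(dz, dz[0], atol=1e-3):
            k = int(np.argmax(np.abs(dz - np.median(dz))))
            raise ValueError(
                f"non-uniform slice spacing: gap of {dz[k]:.3f} mm between "
                f"z={zs[k]:.3f} and z={zs[k + 1]:.3f} (expected {np.median(dz):.3f})"
            )
        slice_spacing = float(dz[0])
    else:
        slice_spacing = float(slices[0][1].get("SliceThickness", 1.0))
    first = slices[0][1]
    rows, cols = int(first.Rows), int(first.Columns)
    dy, dx = first.PixelSpacing
    hu = np.empty((len(slices), rows, cols), dtype=np.float64)
    for i, (f, ds) in enumerate(slices):
        raw = np.frombuffer(ds.PixelData, dtype="<i2").reshape(rows, cols)
        slope = float(ds.get("RescaleSlope", 1.0))
        intercept = float(ds.get("RescaleIntercept", 0.0))
        hu[i] = raw * slope + intercept
    ipp = first.ImagePositionPatient
    geom = Geometry(origin=(float(ipp[0]), float(ipp[1]), float(zs[0])),
                    spacing=(float(dx), float(dy), slice_spacing),
                    shape=(len(slices), rows, cols))
    hu_int = np.rint(hu)
    if np.allclose(hu, hu_int):
        hu = hu_int.astype(np.int16)
    return CTVolume(hu=hu, geometry=geom)


# ---------------------------------------------------------------------------
# RT Plan
# ---------------------------------------------------------------------------

def _energy_label(cp0: _dicom.Dataset, beam: _dicom.Dataset) -> str:
    energy = cp0.get("NominalBeamEnergy")
    if energy is None:
        raise ValueError("control point 0 missing NominalBeamEnergy")
    label = f"{int(round(float(energy)))}X"
    for item in beam.get("PrimaryFluenceModeSequence", []) or []:
        if item.get("FluenceMode") == "NON_STANDARD" and item.get("FluenceModeID") == "FFF":
            label = f"{int(round(float(energy)))}FFF"
    return label


def read_rtplan(path) -> VMATPlan:
    """Parse an RT Plan file into a :class:`VMATPlan`.

    Per-control-point state (gantry, jaws, MLC, cumulative weight) is
    populated with DICOM's carry-forward semantics: attributes omitted at
    a control point inherit the previous value.
    """
    ds = _dicom.read_file(path)
    if "BeamSequence" not in ds:
        raise ValueError(f"{path}: no BeamSequence")
    mu_by_number: dict[int, float] = {}
    for fg in ds.get("FractionGroupSequence", []) or []:
        for rb in fg.get("ReferencedBeamSequence", []) or []:
            mu_by_number[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams: list[ArcBeam] = []
    for beam in ds.BeamSequence:
        if beam.get("TreatmentDeliveryType", "TREATMENT") != "TREATMENT":
            continue
        number = int(beam.get("BeamNumber", len(beams) + 1))
        name = str(beam.get("BeamName", f"beam{number}"))
        cps = beam.get("ControlPointSequence")
        if not cps:
            raise ValueError(f"beam {name}: missing control point sequence")
        leaf_boundaries = None
        n_pairs = None
        for bld in beam.get("BeamLimitingDeviceSequence", []) or []:
            if str(bld.get("RTBeamLimitingDeviceType", "")).startswith("MLC"):
                leaf_boundaries = np.asarray(bld.LeafPositionBoundaries, dtype=float)
                n_pairs = int(bld.get("NumberOfLeafJawPairs", len(leaf_boundaries) - 1))
        if leaf_boundaries is None:
            raise ValueError(f"beam {name}: no MLC in BeamLimitingDeviceSequence")

        final_w = float(beam.get("FinalCumulativeMetersetWeight", 1.0))
        unsupported: list[str] = []
        gantry = jaws_x = jaws_y = mlc = None
        collimator = couch = None
        control_points: list[ControlPoint] = []
        raw_weights: list[float] = []
        for k, cp in enumerate(cps):
            gantry = float(cp.get("GantryAngle", gantry if gantry is not None else 0.0))
            for dev in cp.get("BeamLimitingDevicePositionSequence", []) or []:
                kind = str(dev.RTBeamLimitingDeviceType)
                pos = np.asarray(dev.LeafJawPositions, dtype=float)
                if kind in ("X", "ASYMX"):
                    jaws_x = (float(pos[0]), float(pos[1]))
                elif kind in ("Y", "ASYMY"):
                    jaws_y = (float(pos[0]), float(pos[1]))
                elif kind.startswith("MLC"):
                    mlc = pos.reshape(2, -1)
            if jaws_x is None or jaws_y is None or mlc is None:
                raise ValueError(f"beam {name} CP {k}: jaw/MLC state unresolved")
            if n_pairs is not None and mlc.shape[1] != n_pairs:
                raise ValueError(f"beam {name} CP {k}: {mlc.shape[1]} leaf pairs, expected {n_pairs}")
            w = float(cp.get("CumulativeMetersetWeight", 0.0))
            raw_weights.append(w)
            if k > 0 and w < raw_weights[k - 1] - 1e-9:
                raise ValueError(f"beam {name}: cumulative weight decreases at CP {k}")
            new_coll = float(cp.get("BeamLimitingDeviceAngle", collimator if collimator is not None else 0.0))
            new_couch = float(cp.get("PatientSupportAngle", couch if couch is not None else 0.0))
            if collimator is not None and new_coll != collimator:
                unsupported.append(f"collimator rotation change at CP {k}")
            if couch is not None and new_couch != couch:
                unsupported.append(f"couch angle change at CP {k}")
            collimator, couch = new_coll, new_couch
            point = ControlPoint(
                gantry_deg=gantry,
                jaws=(jaws_x[0], jaws_x[1], jaws_y[0], jaws_y[1]),
                mlc=mlc.copy(),
                cum_weight=w / final_w if final_w else 0.0,
            )
            crossed = point.crossed_pairs()
            if crossed.size:
                raise ValueError(
                    f"beam {name} CP {k}: crossed leaves at pair(s) {crossed.tolist()}"
                )
            control_points.append(point)

        gantries = np.array([c.gantry_deg for c in control_points])
        is_arc = not np.allclose(gantries, gantries[0])
        beams.append(
            ArcBeam(
                energy=_energy_label(cps[0], beam),
                beam_mu=mu_by_number.get(number, 0.0),
                control_points=control_points,
                leaf_boundaries=leaf_boundaries,
                beam_number=number,
                name=name,
                is_arc=is_arc,
                unsupported=unsupported,
            )
        )
    if not beams:
        raise ValueError(f"{path}: no treatment beams")
    return VMATPlan(beams=beams, label=str(ds.get("RTPlanLabel", "plan")))


# ---------------------------------------------------------------------------
# RT Structure Set
# ---------------------------------------------------------------------------

def _rasterize_polygon(xy: np.ndarray, geom: Geometry) -> np.ndarray:
    """Even-odd rasterization of one closed polygon onto the in-plane grid."""
    from matplotlib.path import Path as MplPath

    nz, ny, nx = geom.shape
    xs = geom.axis_centers(0)
    ys = geom.axis_centers(1)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(xy).contains_points(pts)
    return inside.reshape(ny, nx)


def read_structures(path, ct: CTVolume) -> StructureSet:
    """Load an RT Structure Set and rasterize contours onto the CT grid."""
    import warnings

    ds = _dicom.read_file(path)
    names = {}
    for roi in ds.get("StructureSetROISequence", []) or []:
        names[int(roi.ROINumber)] = str(roi.ROIName)
    rois: dict[str, ROI] = {}
    geom = ct.geometry
    zs = geom.axis_centers(2)
    for rc in ds.get("ROIContourSequence", []) or []:
        number = int(rc.ReferencedROINumber)
        name = names.get(number, f"ROI{number}")
        contours = []
        mask = np.zeros(geom.shape, dtype=bool)
        seq = rc.get("ContourSequence", []) or []
        if not seq:
            warnings.warn(f"ROI {name!r} has no contours; mask is empty", stacklevel=2)
        for c in seq:
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append(data)
            iz = int(np.argmin(np.abs(zs - data[0, 2])))
            if abs(zs[iz] - data[0, 2]) > geom.spacing[2]:
                continue  # contour plane outside CT
            mask[iz] ^= _rasterize_polygon(data[:, :2], geom)
        rois[name] = ROI(name=name, mask=mask, geometry=geom, contours=contours)
    return StructureSet(rois=rois)


# ---------------------------------------------------------------------------
# RT Dose
# ---------------------------------------------------------------------------

def read_rtdose(path) -> TPSDose:
    ds = _dicom.read_file(path)
    rows, cols = int(ds.Rows), int(ds.Columns)
    nframes = int(ds.get("NumberOfFrames", 1))
    bits = int(ds.get("BitsAllocated", 32))
    dtype = {16: "<u2", 32: "<u4"}[bits]
    raw = np.frombuffer(ds.PixelData, dtype=dtype).reshape(nframes, rows, cols)
    scaling = float(ds.DoseGridScaling)
    dose = raw.astype(np.float64) * scaling
    ipp = ds.ImagePositionPatient
    dy, dx = ds.PixelSpacing
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        dz = np.diff(offsets)
        if not np.allclose(dz, dz[0], atol=1e-6):
            raise ValueError("non-uniform GridFrameOffsetVector")
        dzv = float(dz[0])
    else:
        dzv = float(ds.get("SliceThickness", 1.0))
    geom = Geometry(origin=(float(ipp[0]), float(ipp[1]), float(ipp[2]) + float(offsets[0])),
                    spacing=(float(dx), float(dy), dzv),
                    shape=(nframes, rows, cols))
    return TPSDose(dose=dose, geometry=geom)


def write_rtdose(path, dose: np.ndarray, geometry: Geometry, *,
                 plan_uid: str | None = None, scaling: float | None = None,
                 study_uid: str | None = None, frame_uid: str | None = None) -> float:
    """Write a calibrated Gy dose grid as an RT Dose file.

    Dose is quantized to 32-bit unsigned integers with the stored
    ``DoseGridScaling``; the round trip error is at most one quantization
    step.  Returns the scaling actually used.
    """
    dose = np.asarray(dose, dtype=float)
    if dose.shape != geometry.shape:
        raise ValueError("dose shape does not match geometry")
    if np.any(~np.isfinite(dose)) or np.any(dose < 0):
        raise ValueError("dose must be finite and non-negative")
    max_int = 2**32 - 1
    dmax = float(dose.max())
    if scaling is None:
        scaling = dmax / max_int if dmax > 0 else 1e-9
    if dmax > 0 and dmax / scaling > max_int + 0.5:
        raise ValueError(
            f"dose max {dmax:.4g} Gy exceeds representable range at scaling {scaling:.4g}"
        )
    quantized = np.rint(dose / scaling).astype("<u4") if dmax > 0 else np.zeros_like(dose, dtype="<u4")
    nz, ny, nx = geometry.shape
    ds = _dicom.Dataset(
        SOPClassUID=RTDOSE_SOP_CLASS,
        SOPInstanceUID=_dicom.generate_uid(),
        StudyInstanceUID=study_uid or _dicom.generate_uid(),
        SeriesInstanceUID=_dicom.generate_uid(),
        FrameOfReferenceUID=frame_uid or _dicom.generate_uid(),
        Modality="RTDOSE",
        PatientName="MUV^CASE",
        PatientID="MUV",
        SamplesPerPixel=1,
        PhotometricInterpretation="MONOCHROME2",
        NumberOfFrames=nz,
        Rows=ny,
        Columns=nx,
        PixelSpacing=[geometry.spacing[1], geometry.spacing[0]],
        ImagePositionPatient=list(geometry.origin),
        ImageOrientationPatient=[1, 0, 0, 0, 1, 0],
        BitsAllocated=32,
        BitsStored=32,
        HighBit=31,
        PixelRepresentation=0,
        DoseUnits="GY",
        DoseType="PHYSICAL",
        DoseSummationType="PLAN",
        GridFrameOffsetVector=[i * geometry.spacing[2] for i in range(nz)],
        DoseGridScaling=scaling,
        PixelData=quantized.tobytes(),
    )
    _dicom.write_file(path, ds)
    return scaling


# ---------------------------------------------------------------------------
# de-identification
# ---------------------------------------------------------------------------

_IDENTIFYING = [
    "PatientBirthDate", "PatientSex", "ReferringPhysicianName", "OperatorsName",
    "InstitutionName", "StationName", "AccessionNumber",
]
_UID_KEYWORDS = [
    "StudyInstanceUID", "SeriesInstanceUID", "FrameOfReferenceUID",
    "SOPInstanceUID", "MediaStorageSOPInstanceUID", "ReferencedFrameOfReferenceUID",
]
_DEID_MARKER = "MUV-DEID"


def _remap_uids(ds: _dicom.Dataset, mapping: dict[str, str]) -> None:
    for kw in _UID_KEYWORDS:
        if kw in ds:
            old = getattr(ds, kw)
            if old not in mapping:
                import hashlib

                digest = hashlib.sha1(old.encode()).hexdigest()[:16]
                mapping[old] = f"{_dicom.UID_ROOT}.9.{int(digest, 16)}"
            setattr(ds, kw, mapping[old])
    for (g, e), (vr, value) in list(ds.items()):
        if vr == "SQ":
            for item in value:
                _remap_uids(item, mapping)


def strip_identifiers(files, out_dir) -> list[Path]:
    """De-identify a set of DICOM files with consistent UID remapping.

    Identifying tags are replaced or removed; every UID is remapped through
    one per-call bijection so cross-references survive.  Files already
    carrying the de-identification marker are copied through unchanged.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mapping: dict[str, str] = {}
    outputs = []
    for f in map(Path, files):
        ds = _dicom.read_file(f)
        out = out_dir / f.name
        if ds.get("DeidentificationMethod") == _DEID_MARKER:
            out.write_bytes(f.read_bytes())
            outputs.append(out)
            continue
        if "PatientName" in ds:
            ds.PatientName = "ANON^ANON"
        if "PatientID" in ds:
            ds.PatientID = "ANON"
        for kw in _IDENTIFYING:
            ds.pop(kw)
        _remap_uids(ds, mapping)
        ds.DeidentificationMethod = _DEID_MARKER
        _dicom.write_file(out, ds)
        outputs.append(out)
    return outputs


# ---------------------------------------------------------------------------
# case container (HDF5)
# ---------------------------------------------------------------------------

def _geom_to_attrs(group, geom: Geometry) -> None:
    group.attrs["origin"] = geom.origin
    group.attrs["spacing"] = geom.spacing
    group.attrs["shape"] = geom.shape


def _geom_from_attrs(group) -> Geometry:
    return Geometry(origin=tuple(group.attrs["origin"]),
                    spacing=tuple(group.attrs["spacing"]),
                    shape=tuple(int(n) for n in group.attrs["shape"]))


def plan_to_dict(plan: VMATPlan) -> dict:
    return {
        "label": plan.label,
        "beams": [
            {
                "energy": b.energy,
                "beam_mu": b.beam_mu,
                "beam_number": b.beam_number,
                "name": b.name,
                "is_arc": b.is_arc,
                "unsupported": b.unsupported,
                "leaf_boundaries": b.leaf_boundaries.tolist(),
                "control_points": [
                    {
                        "gantry_deg": cp.gantry_deg,
                        "jaws": list(cp.jaws),
                        "mlc": cp.mlc.tolist(),
                        "cum_weight": cp.cum_weight,
                    }
                    for cp in b.control_points
                ],
            }
            for b in plan.beams
        ],
    }


def plan_from_dict(d: dict) -> VMATPlan:
    beams = []
    for b in d["beams"]:
        beams.append(
            ArcBeam(
                energy=b["energy"],
                beam_mu=b["beam_mu"],
                control_points=[
                    ControlPoint(
                        gantry_deg=cp["gantry_deg"],
                        jaws=tuple(cp["jaws"]),
                        mlc=np.asarray(cp["mlc"]),
                        cum_weight=cp["cum_weight"],
                    )
                    for cp in b["control_points"]
                ],
                leaf_boundaries=np.asarray(b["leaf_boundaries"]),
                beam_number=b["beam_number"],
                name=b["name"],
                is_arc=b["is_arc"],
                unsupported=list(b["unsupported"]),
            )
        )
    return VMATPlan(beams=beams, label=d.get("label", "plan"))


def write_case(path, *, ct: CTVolume, plan: VMATPlan | None = None,
               structures: StructureSet | None = None,
               tps_dose: TPSDose | None = None) -> None:
    """Bundle the loaded objects into one HDF5 case container.

    Layout: ``/ct/hu`` with geometry attrs; ``/plan`` (JSON attr);
    ``/structures/<name>`` boolean masks; ``/tps_dose/dose``.
    """
    import h5py

    with h5py.File(path, "w") as h5:
        g = h5.create_group("ct")
        g.create_dataset("hu", data=ct.hu, compression="gzip")
        _geom_to_attrs(g, ct.geometry)
        if plan is not None:
            h5.create_group("plan").attrs["json"] = json.dumps(plan_to_dict(plan))
        if structures is not None:
            sg = h5.create_group("structures")
            for name, roi in structures.rois.items():
                d = sg.create_dataset(name, data=roi.mask, compression="gzip")
                d.attrs["origin"] = roi.geometry.origin
                d.attrs["spacing"] = roi.geometry.spacing
        if tps_dose is not None:
            dg = h5.create_group("tps_dose")
            dg.create_dataset("dose", data=tps_dose.dose, compression="gzip")
            _geom_to_attrs(dg, tps_dose.geometry)


def read_case(path) -> dict:
    import h5py

    out: dict = {}
    with h5py.File(path, "r") as h5:
        g = h5["ct"]
        out["ct"] = CTVolume(hu=g["hu"][...], geometry=_geom_from_attrs(g))
        if "plan" in h5:
            out["plan"] = plan_from_dict(json.loads(h5["plan"].attrs["json"]))
        if "structures" in h5:
            rois = {}
            for name, d in h5["structures"].items():
                geom = Geometry(origin=tuple(d.attrs["origin"]),
                                spacing=tuple(d.attrs["spacing"]),
                                shape=d.shape)
                rois[name] = ROI(name=name, mask=d[...], geometry=geom)
            out["structures"] = StructureSet(rois=rois)
        if "tps_dose" in h5:
            dg = h5["tps_dose"]
            out["tps_dose"] = TPSDose(dose=dg["dose"][...], geometry=_geom_from_attrs(dg))
    return out
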