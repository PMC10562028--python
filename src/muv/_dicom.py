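"""Minimal DICOM codec: Explicit VR Little Endian read/write.

Self-contained encoder/decoder for the subset of the DICOM standard the
pipeline touches (CT Image, RT Plan, RT Structure Set, RT Dose).  Only the
Explicit VR Little Endian transfer syntax (1.2.840.10008.1.2.1) is
supported; files written by :func:`write_file` always use it.  Sequences
are written with defined lengths but both defined- and undefined-length
sequences/items are readable.

This is not a general DICOM implementation — unknown tags round-trip as
raw bytes, and no charset handling beyond ASCII is attempted.
"""

from __future__ import annotations

import struct
from io import BytesIO
from typing import Any, BinaryIO

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"
UID_ROOT = "1.2.826.0.1.3680043.10.1457"  # generic org root for generated UIDs

# VRs with a 2-byte reserved field and 4-byte length
_LONG_VRS = {"OB", "OW", "OF", "OD", "OL", "SQ", "UC", "UR", "UT", "UN"}

# keyword -> (group, element, VR, multi)  multi: value is a list
_DICT: dict[str, tuple[int, int, str, bool]] = {
    # file meta
    "FileMetaInformationGroupLength": (0x0002, 0x0000, "UL", False),
    "MediaStorageSOPClassUID": (0x0002, 0x0002, "UI", False),
    "MediaStorageSOPInstanceUID": (0x0002, 0x0003, "UI", False),
    "TransferSyntaxUID": (0x0002, 0x0010, "UI", False),
    "ImplementationClassUID": (0x0002, 0x0012, "UI", False),
    # identity / study
    "SpecificCharacterSet": (0x0008, 0x0005, "CS", False),
    "SOPClassUID": (0x0008, 0x0016, "UI", False),
    "SOPInstanceUID": (0x0008, 0x0018, "UI", False),
    "StudyDate": (0x0008, 0x0020, "DA", False),
    "StudyTime": (0x0008, 0x0030, "TM", False),
    "AccessionNumber": (0x0008, 0x0050, "SH", False),
    "Modality": (0x0008, 0x0060, "CS", False),
    "Manufacturer": (0x0008, 0x0070, "LO", False),
    "ReferringPhysicianName": (0x0008, 0x0090, "PN", False),
    "StationName": (0x0008, 0x1010, "SH", False),
    "StudyDescription": (0x0008, 0x1030, "LO", False),
    "SeriesDescription": (0x0008, 0x103E, "LO", False),
    "InstitutionName": (0x0008, 0x0080, "LO", False),
    "OperatorsName": (0x0008, 0x1070, "PN", False),
    "PatientName": (0x0010, 0x0010, "PN", False),
    "PatientID": (0x0010, 0x0020, "LO", False),
    "PatientBirthDate": (0x0010, 0x0030, "DA", False),
    "PatientSex": (0x0010, 0x0040, "CS", False),
    "DeidentificationMethod": (0x0012, 0x0063, "LO", False),
    # geometry
    "SliceThickness": (0x0018, 0x0050, "DS", False),
    "StudyInstanceUID": (0x0020, 0x000D, "UI", False),
    "SeriesInstanceUID": (0x0020, 0x000E, "UI", False),
    "SeriesNumber": (0x0020, 0x0011, "IS", False),
    "InstanceNumber": (0x0020, 0x0013, "IS", False),
    "ImagePositionPatient": (0x0020, 0x0032, "DS", True),
    "ImageOrientationPatient": (0x0020, 0x0037, "DS", True),
    "FrameOfReferenceUID": (0x0020, 0x0052, "UI", False),
    "PositionReferenceIndicator": (0x0020, 0x1040, "LO", False),
    # image pixel
    "SamplesPerPixel": (0x0028, 0x0002, "US", False),
    "PhotometricInterpretation": (0x0028, 0x0004, "CS", False),
    "NumberOfFrames": (0x0028, 0x0008, "IS", False),
    "Rows": (0x0028, 0x0010, "US", False),
    "Columns": (0x0028, 0x0011, "US", False),
    "PixelSpacing": (0x0028, 0x0030, "DS", True),
    "BitsAllocated": (0x0028, 0x0100, "US", False),
    "BitsStored": (0x0028, 0x0101, "US", False),
    "HighBit": (0x0028, 0x0102, "US", False),
    "PixelRepresentation": (0x0028, 0x0103, "US", False),
    "RescaleIntercept": (0x0028, 0x1052, "DS", False),
    "RescaleSlope": (0x0028, 0x1053, "DS", False),
    # RT dose
    "DoseUnits": (0x3004, 0x0002, "CS", False),
    "DoseType": (0x3004, 0x0004, "CS", False),
    "DoseSummationType": (0x3004, 0x000A, "CS", False),
    "GridFrameOffsetVector": (0x3004, 0x000C, "DS", True),
    "DoseGridScaling": (0x3004, 0x000E, "DS", False),
    # RT structure set
    "StructureSetLabel": (0x3006, 0x0002, "SH", False),
    "ReferencedFrameOfReferenceSequence": (0x3006, 0x0010, "SQ", False),
    "StructureSetROISequence": (0x3006, 0x0020, "SQ", False),
    "ROINumber": (0x3006, 0x0022, "IS", False),
    "ReferencedFrameOfReferenceUID": (0x3006, 0x0024, "UI", False),
    "ROIName": (0x3006, 0x0026, "LO", False),
    "ROIContourSequence": (0x3006, 0x0039, "SQ", False),
    "ContourSequence": (0x3006, 0x0040, "SQ", False),
    "ContourGeometricType": (0x3006, 0x0042, "CS", False),
    "NumberOfContourPoints": (0x3006, 0x0046, "IS", False),
    "ContourData": (0x3006, 0x0050, "DS", True),
    "ReferencedROINumber": (0x3006, 0x0084, "IS", False),
    # RT plan
    "RTPlanLabel": (0x300A, 0x0002, "SH", False),
    "RTPlanDate": (0x300A, 0x0006, "DA", False),
    "RTPlanGeometry": (0x300A, 0x000C, "CS", False),
    "FractionGroupSequence": (0x300A, 0x0070, "SQ", False),
    "FractionGroupNumber": (0x300A, 0x0071, "IS", False),
    "NumberOfFractionsPlanned": (0x300A, 0x0078, "IS", False),
    "NumberOfBeams": (0x300A, 0x0080, "IS", False),
    "BeamDoseSpecificationPoint": (0x300A, 0x0082, "DS", True),
    "BeamDose": (0x300A, 0x0084, "DS", False),
    "BeamMeterset": (0x300A, 0x0086, "DS", False),
    "BeamSequence": (0x300A, 0x00B0, "SQ", False),
    "BeamLimitingDeviceSequence": (0x300A, 0x00B6, "SQ", False),
    "RTBeamLimitingDeviceType": (0x300A, 0x00B8, "CS", False),
    "NumberOfLeafJawPairs": (0x300A, 0x00BC, "IS", False),
    "LeafPositionBoundaries": (0x300A, 0x00BE, "DS", True),
    "BeamNumber": (0x300A, 0x00C0, "IS", False),
    "BeamName": (0x300A, 0x00C2, "LO", False),
    "BeamType": (0x300A, 0x00C4, "CS", False),
    "RadiationType": (0x300A, 0x00C6, "CS", False),
    "TreatmentMachineName": (0x300A, 0x00B2, "SH", False),
    "SourceAxisDistance": (0x300A, 0x00B4, "DS", False),
    "PrimaryFluenceModeSequence": (0x300A, 0x0030, "SQ", False),
    "FluenceMode": (0x3002, 0x0051, "CS", False),
    "FluenceModeID": (0x3002, 0x0052, "SH", False),
    "FinalCumulativeMetersetWeight": (0x300A, 0x010E, "DS", False),
    "NumberOfControlPoints": (0x300A, 0x0110, "IS", False),
    "ControlPointSequence": (0x300A, 0x0111, "SQ", False),
    "ControlPointIndex": (0x300A, 0x0112, "IS", False),
    "NominalBeamEnergy": (0x300A, 0x0114, "DS", False),
    "BeamLimitingDevicePositionSequence": (0x300A, 0x011A, "SQ", False),
    "LeafJawPositions": (0x300A, 0x011C, "DS", True),
    "GantryAngle": (0x300A, 0x011E, "DS", False),
    "GantryRotationDirection": (0x300A, 0x011F, "CS", False),
    "BeamLimitingDeviceAngle": (0x300A, 0x0120, "DS", False),
    "BeamLimitingDeviceRotationDirection": (0x300A, 0x0121, "CS", False),
    "PatientSupportAngle": (0x300A, 0x0122, "DS", False),
    "PatientSupportRotationDirection": (0x300A, 0x0123, "CS", False),
    "IsocenterPosition": (0x300A, 0x012C, "DS", True),
    "CumulativeMetersetWeight": (0x300A, 0x0134, "DS", False),
    "TreatmentDeliveryType": (0x300A, 0x00CE, "CS", False),
    "ReferencedBeamSequence": (0x300C, 0x0004, "SQ", False),
    "ReferencedBeamNumber": (0x300C, 0x0006, "IS", False),
    # pixel data
    "PixelData": (0x7FE0, 0x0010, "OW", False),
}

_TAG_TO_KEYWORD = {(g, e): (kw, vr, multi) for kw, (g, e, vr, multi) in _DICT.items()}

_STR_VRS = {"AE", "AS", "CS", "DA", "DT", "LO", "LT", "PN", "SH", "ST", "TM", "UC", "UR", "UT", "UI"}
_FLOAT_VRS = {"DS", "FL", "FD"}
_INT_VRS = {"IS", "SL", "SS", "UL", "US"}


def tag_for(keyword: str) -> tuple[int, int]:
    g, e, _, _ = _DICT[keyword]
    return g, e


class Dataset:
    """An ordered mapping of DICOM tags to decoded values.

    Known tags are exposed as attributes by keyword; unknown tags survive
    round-trips as raw ``bytes`` keyed by ``(group, element)``.
    """

    def __init__(self, **kwargs: Any):
        self._elements: dict[tuple[int, int], tuple[str, Any]] = {}
        for k, v in kwargs.items():
            setattr(self, k, v)

    # -- attribute interface -------------------------------------------------
    def __setattr__(self, name: str, value: Any) -> None:
        if name.startswith("_"):
            object.__setattr__(self, name, value)
            return
        if name not in _DICT:
            raise AttributeError(f"unknown DICOM keyword {name!r}")
        g, e, vr, _ = _DICT[name]
        self._elements[(g, e)] = (vr, value)

    def __getattr__(self, name: str) -> Any:
        if name.startswith("_"):
            raise AttributeError(name)
        if name in _DICT:
            g, e, _, _ = _DICT[name]
            try:
                return self._elements[(g, e)][1]
            except KeyError:
                raise AttributeError(f"dataset has no element {name!r}") from None
        raise AttributeError(name)

    def __contains__(self, keyword: str) -> bool:
        return keyword in _DICT and tag_for(keyword) in self._elements

    def get(self, keyword: str, default: Any = None) -> Any:
        return getattr(self, keyword) if keyword in self else default

    def pop(self, keyword: str, default: Any = None) -> Any:
        return self._elements.pop(tag_for(keyword), (None, default))[1]

    def set_raw(self, tag: tuple[int, int], vr: str, value: Any) -> None:
        self._elements[tag] = (vr, value)

    def items(self):
        return sorted(self._elements.items())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Dataset) and self._elements == other._elements

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        lines = []
        for (g, e), (vr, v) in self.items():
            kw = _TAG_TO_KEYWORD.get((g, e), ("?",))[0]
            sv = f"<{len(v)} bytes>" if isinstance(v, bytes) else repr(v)
            lines.append(f"({g:04X},{e:04X}) {vr} {kw}: {sv}")
        return "\n".join(lines)


# -- value encoding ----------------------------------------------------------

def _format_number(x: Any) -> str:
    if isinstance(x, int):
        return str(x)
    s = f"{float(x):.10g}"
    return s[:16]


def _encode_value(vr: str, value: Any) -> bytes:
    if vr == "SQ":
        raise ValueError("sequences handled separately")
    if isinstance(value, bytes):
        data = value
    elif vr in ("DS", "IS"):
        if isinstance(value, (list, tuple)):
            data = "\\".join(_format_number(v) for v in value).encode("ascii")
        else:
            data = _format_number(value).encode("ascii")
    elif vr in _STR_VRS:
        if isinstance(value, (list, tuple)):
            data = "\\".join(str(v) for v in value).encode("ascii")
        else:
            data = str(value).encode("ascii")
    elif vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        data = struct.pack(f"<{len(vals)}H", *[int(v) for v in vals])
    elif vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        data = struct.pack(f"<{len(vals)}I", *[int(v) for v in vals])
    elif vr == "SS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        data = struct.pack(f"<{len(vals)}h", *[int(v) for v in vals])
    elif vr == "FL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        data = struct.pack(f"<{len(vals)}f", *[float(v) for v in vals])
    elif vr == "FD":
        vals = value if isinstance(value, (list, tuple)) else [value]
        data = struct.pack(f"<{len(vals)}d", *[float(v) for v in vals])
    else:
        raise ValueError(f"cannot encode VR {vr}")
    if len(data) % 2:
        data += b"\x00" if vr in ("UI", "OB") else b" "
    return data


def _decode_value(vr: str, data: bytes, multi: bool) -> Any:
    if vr in ("OB", "OW", "OF", "UN", "OD", "OL"):
        return data
    if vr in ("US", "UL", "SS", "SL", "FL", "FD"):
        fmt, size = {"US": ("H", 2), "UL": ("I", 4), "SS": ("h", 2),
                     "SL": ("i", 4), "FL": ("f", 4), "FD": ("d", 8)}[vr]
        n = len(data) // size
        vals = list(struct.unpack(f"<{n}{fmt}", data[: n * size]))
        return vals if (multi or n > 1) else (vals[0] if vals else None)
    text = data.decode("ascii", errors="replace")
    if vr == "UI":
        text = text.rstrip("\x00")
    text = text.strip()
    if vr == "DS":
        vals = [float(t) for t in text.split("\\") if t.strip()]
        return vals if multi else (vals[0] if vals else None)
    if vr == "IS":
        vals = [int(t) for t in text.split("\\") if t.strip()]
        return vals if multi else (vals[0] if vals else None)
    if "\\" in text:
        return text.split("\\")
    return text


# -- element / dataset serialisation ----------------------------------------

def _write_element(buf: BytesIO, group: int, elem: int, vr: str, value: Any) -> None:
    if vr == "SQ":
        payload = BytesIO()
        for item in value:
            item_bytes = _dataset_bytes(item)
            payload.write(struct.pack("<HHI", 0xFFFE, 0xE000, len(item_bytes)))
            payload.write(item_bytes)
        data = payload.getvalue()
        buf.write(struct.pack("<HH", group, elem))
        buf.write(vr.encode("ascii"))
        buf.write(struct.pack("<HI", 0, len(data)))
        buf.write(data)
        return
    data = _encode_value(vr, value)
    buf.write(struct.pack("<HH", group, elem))
    buf.write(vr.encode("ascii"))
    if vr in _LONG_VRS:
        buf.write(struct.pack("<HI", 0, len(data)))
    else:
        if len(data) > 0xFFFF:
            raise ValueError(f"value too long for short VR {vr}")
        buf.write(struct.pack("<H", len(data)))
    buf.write(data)


def _dataset_bytes(ds: Dataset) -> bytes:
    buf = BytesIO()
    for (g, e), (vr, value) in ds.items():
        if g == 0x0002:
            continue
        _write_element(buf, g, e, vr, value)
    return buf.getvalue()


def write_file(path, ds: Dataset) -> None:
    """Serialize *ds* as a Part-10 file (Explicit VR Little Endian)."""
    sop_class = ds.get("SOPClassUID", "1.2.840.10008.5.1.4.1.1.2")
    sop_inst = ds.get("SOPInstanceUID", generate_uid("0"))
    meta = BytesIO()
    for kw, val in [
        ("MediaStorageSOPClassUID", sop_class),
        ("MediaStorageSOPInstanceUID", sop_inst),
        ("TransferSyntaxUID", TRANSFER_SYNTAX_EXPLICIT_LE),
        ("ImplementationClassUID", UID_ROOT + ".1"),
    ]:
        g, e, vr, _ = _DICT[kw]
        _write_element(meta, g, e, vr, val)
    meta_bytes = meta.getvalue()
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        hdr = BytesIO()
        _write_element(hdr, 0x0002, 0x0000, "UL", len(meta_bytes))
        fh.write(hdr.getvalue())
        fh.write(meta_bytes)
        fh.write(_dataset_bytes(ds))


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def u16(self) -> int:
        v = struct.unpack_from("<H", self.data, self.pos)[0]
        self.pos += 2
        return v

    def u32(self) -> int:
        v = struct.unpack_from("<I", self.data, self.pos)[0]
        self.pos += 4
        return v

    def raw(self, n: int) -> bytes:
        v = self.data[self.pos: self.pos + n]
        self.pos += n
        return v

    @property
    def remaining(self) -> int:
        return len(self.data) - self.pos


def _read_dataset(r: _Reader, end: int) -> Dataset:
    ds = Dataset()
    while r.pos < end:
        group = r.u16()
        elem = r.u16()
        if (group, elem) == (0xFFFE, 0xE00D):  # item delimiter
            r.u32()
            break
        vr = r.raw(2).decode("ascii")
        if vr in _LONG_VRS:
            r.u16()
            length = r.u32()
        else:
            length = r.u16()
        if vr == "SQ":
            items = _read_sequence(r, length)
            ds.set_raw((group, elem), "SQ", items)
            continue
        if length == 0xFFFFFFFF:
            raise ValueError("undefined length only supported for SQ")
        data = r.raw(length)
        known = _TAG_TO_KEYWORD.get((group, elem))
        multi = known[2] if known else False
        ds.set_raw((group, elem), vr, _decode_value(vr, data, multi))
    return ds


def _read_sequence(r: _Reader, length: int) -> list[Dataset]:
    items: list[Dataset] = []
    end = len(r.data) if length == 0xFFFFFFFF else r.pos + length
    while r.pos < end:
        group = r.u16()
        elem = r.u16()
        ilen = r.u32()
        if (group, elem) == (0xFFFE, 0xE0DD):  # sequence delimiter
            break
        if (group, elem) != (0xFFFE, 0xE000):
            raise ValueError(f"malformed sequence item tag ({group:04X},{elem:04X})")
        item_end = len(r.data) if ilen == 0xFFFFFFFF else r.pos + ilen
        items.append(_read_dataset(r, item_end))
    return items


def read_file(path) -> Dataset:
    """Parse a Part-10 Explicit VR Little Endian file into a :class:`Dataset`."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[128:132] != b"DICM":
        raise ValueError(f"{path}: not a DICOM Part-10 file (missing DICM marker)")
    r = _Reader(blob)
    r.pos = 132
    # file meta group (always explicit LE)
    meta = Dataset()
    while r.remaining:
        group = struct.unpack_from("<H", r.data, r.pos)[0]
        if group != 0x0002:
            break
        r.u16()
        elem = r.u16()
        vr = r.raw(2).decode("ascii")
        if vr in _LONG_VRS:
            r.u16()
            length = r.u32()
        else:
            length = r.u16()
        data = r.raw(length)
        known = _TAG_TO_KEYWORD.get((0x0002, elem))
        meta.set_raw((0x0002, elem), vr, _decode_value(vr, data, known[2] if known else False))
    ts = meta.get("TransferSyntaxUID", TRANSFER_SYNTAX_EXPLICIT_LE)
    if ts != TRANSFER_SYNTAX_EXPLICIT_LE:
        raise ValueError(f"unsupported transfer syntax {ts}")
    ds = _read_dataset(r, len(blob))
    for tag, (vr, val) in meta._elements.items():
        ds.set_raw(tag, vr, val)
    return ds


_uid_counter = 0


def generate_uid(suffix: str | None = None) -> str:
    """Deterministic-format UID under the package root."""
    global _uid_counter
    _uid_counter += 1
    import os
    import time

    if suffix is None:
        suffix = f"{os.getpid()}.{int(time.time() * 1e3) % 10**10}.{_uid_counter}"
    return f"{UID_ROOT}.{suffix}"
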