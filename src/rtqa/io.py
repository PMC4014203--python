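"""Readers and writers: DICOM RT Dose / RT Structure Set, the ASCII planar
dose fixture format, correction-table CSVs, and YAML scenario configs.

The canonical internal dose unit is cGy; files in Gy are converted at this
boundary.  All writers and readers are mutually inverse at the documented
precision.

ASCII planar-dose format (one file per plane)::

    # planar-dose v1
    # pitch_mm: 7.62 7.62
    # origin_mm: -118.11 -118.11
    # rows: 32
    # cols: 32
    # gantry_angle_deg: 40
    # units: cGy
    <row of `cols` values, inactive elements written as NA>
    ... (`rows` lines)

Correction-table CSV: ``# key: value`` metadata header lines followed by
``angle_deg,factor`` rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .angular import CorrectionTable
from .core import DoseGrid, PlanarDose, StructureSet, rasterize_contours

__all__ = [
    "read_rtdose", "write_rtdose",
    "read_rtstruct", "write_rtstruct",
    "read_planar_ascii", "write_planar_ascii",
    "read_correction_table", "write_correction_table",
    "read_structure_masks", "write_structure_masks",
]

_RTDOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


# ---------------------------------------------------------------- RT Dose

def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` (cGy).

    Pixel data are scaled by DoseGridScaling; Gy files are converted to cGy.
    The frame geometry must be axis-aligned (identity orientation) with a
    uniform slice spacing from GridFrameOffsetVector.
    """
    ds = pydicom.dcmread(path)
    for tag in ("DoseGridScaling", "PixelSpacing", "ImagePositionPatient",
                "GridFrameOffsetVector", "DoseUnits"):
        if tag not in ds:
            raise ValueError(f"RT Dose file missing required tag {tag}")
    scaling = float(ds.DoseGridScaling)
    # pydicom delivers frames x rows x cols = (z, y, x)
    arr = ds.pixel_array.astype(float) * scaling
    units = str(ds.DoseUnits).upper()
    if units == "GY":
        arr *= 100.0
    elif units != "CGY":
        raise ValueError(f"unsupported DoseUnits {ds.DoseUnits!r}")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if len(dz) and not np.allclose(dz, dz[0]):
        raise ValueError("non-uniform GridFrameOffsetVector is unsupported")
    sz = float(dz[0]) if len(dz) else 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # (y, x)
    ipp = [float(v) for v in ds.ImagePositionPatient]
    values = np.transpose(arr, (2, 1, 0))  # -> (x, y, z)
    # non-UID frame labels travel in SeriesDescription (see write_rtdose)
    frame = str(getattr(ds, "SeriesDescription", "")
                or getattr(ds, "FrameOfReferenceUID", ""))
    return DoseGrid(values, (col_sp, row_sp, sz),
                    (ipp[0], ipp[1], ipp[2] + offsets[0]), frame)


def write_rtdose(dose: DoseGrid, path, units: str = "CGY") -> None:
    """Write a :class:`DoseGrid` as a minimal DICOM RT Dose file."""
    nx, ny, nz = dose.shape
    vals = dose.values
    if units.upper() == "GY":
        vals = vals / 100.0
    elif units.upper() != "CGY":
        raise ValueError(f"unsupported units {units!r}")
    vmax = float(vals.max())
    scaling = vmax / (2 ** 32 - 1) if vmax > 0 else 1.0
    pix = np.round(vals / scaling).astype(np.uint32) if vmax > 0 \
        else np.zeros(dose.shape, dtype=np.uint32)

    meta = pydicom.dataset.FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = units.upper()
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    if dose.frame and all(c in "0123456789." for c in dose.frame):
        ds.FrameOfReferenceUID = dose.frame
    else:
        # free-text frame labels are not legal UIDs; carry them separately
        ds.FrameOfReferenceUID = generate_uid()
        if dose.frame:
            ds.SeriesDescription = dose.frame
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [f"{dose.spacing[1]:.10g}", f"{dose.spacing[0]:.10g}"]
    ds.ImagePositionPatient = [f"{v:.10g}" for v in dose.origin]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.GridFrameOffsetVector = [f"{dose.spacing[2] * k:.10g}" for k in range(nz)]
    ds.DoseGridScaling = f"{scaling:.10g}"  # DS values max 16 characters
    ds.PixelData = np.ascontiguousarray(np.transpose(pix, (2, 1, 0))).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ------------------------------------------------------------ RT Structure

def read_rtstruct(path, grid: DoseGrid,
                  names: list[str] | None = None) -> StructureSet:
    """Read a DICOM RT Structure Set and rasterize it onto ``grid``.

    ``names`` optionally filters the structures kept.  A frame-of-reference
    mismatch with the grid raises; structures without contour data yield an
    empty mask (flagged in ``empty_structures``).
    """
    ds = pydicom.dcmread(path)
    if "StructureSetROISequence" not in ds or "ROIContourSequence" not in ds:
        raise ValueError("file is not an RT Structure Set (missing ROI sequences)")
    roi_names = {}
    for roi in ds.StructureSetROISequence:
        roi_names[int(roi.ROINumber)] = str(roi.ROIName)
        for_uid = str(getattr(roi, "ReferencedFrameOfReferenceUID", ""))
        if for_uid and grid.frame and for_uid != grid.frame:
            raise ValueError(
                f"frame of reference mismatch for ROI {roi.ROIName!r}: "
                f"{for_uid} != {grid.frame}")
    contours: dict[str, list] = {}
    for rc in ds.ROIContourSequence:
        name = roi_names.get(int(rc.ReferencedROINumber))
        if name is None or (names is not None and name not in names):
            continue
        slices = []
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            z = float(pts[0, 2])
            poly = pts[:, :2]
            if not np.allclose(poly[0], poly[-1]):
                poly = np.vstack([poly, poly[0]])  # DICOM leaves contours open
            slices.append((z, poly))
        contours[name] = slices
    return rasterize_contours(contours, grid)


def write_rtstruct(contours: dict[str, list], path,
                   frame: str = "") -> None:
    """Write per-slice polygon stacks as a minimal RT Structure Set.

    ``contours`` maps structure name -> list of ``(z_mm, (M, 2) polygon)``;
    a repeated closing vertex is stripped per DICOM convention.
    """
    meta = pydicom.dataset.FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTSTRUCT_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTSTRUCT_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "rtqa"
    for_uid = frame or generate_uid()

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, (name, slices) in enumerate(contours.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = for_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for z, poly in slices:
            poly = np.asarray(poly, dtype=float)
            if np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            data = []
            for x, y in poly:
                data += [f"{x:.10g}", f"{y:.10g}", f"{z:.10g}"]
            c.ContourData = data
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


# ------------------------------------------------------- ASCII planar dose

_SENTINEL = "NA"


def write_planar_ascii(plane: PlanarDose, path) -> None:
    """Write a planar dose to the ASCII fixture format (cGy, %.10g)."""
    lines = [
        "# planar-dose v1",
        f"# pitch_mm: {plane.pitch[0]:.10g} {plane.pitch[1]:.10g}",
        f"# origin_mm: {plane.origin[0]:.10g} {plane.origin[1]:.10g}",
        f"# rows: {plane.shape[0]}",
        f"# cols: {plane.shape[1]}",
        f"# gantry_angle_deg: "
        f"{'NA' if plane.gantry_angle is None else f'{plane.gantry_angle:.10g}'}",
        "# units: cGy",
    ]
    for i in range(plane.shape[0]):
        row = [
            f"{plane.values[i, j]:.10g}" if plane.active[i, j] else _SENTINEL
            for j in range(plane.shape[1])
        ]
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_planar_ascii(path) -> PlanarDose:
    """Read the ASCII planar dose fixture format; inverse of
    :func:`write_planar_ascii`."""
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for ln, line in enumerate(text):
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                header[k.strip()] = v.strip()
            body_start = ln + 1
        else:
            break
    try:
        pitch = tuple(float(v) for v in header["pitch_mm"].split())
        origin = tuple(float(v) for v in header["origin_mm"].split())
        rows = int(header["rows"])
        cols = int(header["cols"])
        ga = header.get("gantry_angle_deg", "NA")
        gantry = None if ga == "NA" else float(ga)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed planar-dose header: {exc}") from exc

    body = [line for line in text[body_start:] if line.strip()]
    if len(body) != rows:
        raise ValueError(
            f"expected {rows} data rows, found {len(body)} "
            f"(starting at line {body_start + 1})")
    values = np.zeros((rows, cols))
    active = np.ones((rows, cols), dtype=bool)
    for i, line in enumerate(body):
        toks = line.split()
        if len(toks) != cols:
            raise ValueError(
                f"line {body_start + i + 1}: expected {cols} columns, "
                f"found {len(toks)}")
        for j, tok in enumerate(toks):
            if tok == _SENTINEL:
                active[i, j] = False
            else:
                values[i, j] = float(tok)
    return PlanarDose(values, pitch, origin, active, gantry)


# ------------------------------------------------------- correction tables

def write_correction_table(table: CorrectionTable, path) -> None:
    """Write a correction table as a two-column CSV with metadata headers."""
    lines = ["# correction-table v1", f"# sad_mm: {table.sad:.10g}"]
    for k, v in table.metadata.items():
        lines.append(f"# {k}: {v}")
    lines.append("angle_deg,factor")
    for a, f in zip(table.angles, table.factors):
        lines.append(f"{a:.10g},{f:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_correction_table(path) -> CorrectionTable:
    """Read a correction-table CSV; inverse of :func:`write_correction_table`."""
    text = Path(path).read_text().splitlines()
    sad = 1000.0
    metadata: dict[str, str] = {}
    angles, factors = [], []
    seen_header = False
    for ln, line in enumerate(text, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                k, v = k.strip(), v.strip()
                if k == "sad_mm":
                    sad = float(v)
                elif k != "correction-table v1":
                    metadata[k] = v
            continue
        if line == "angle_deg,factor":
            seen_header = True
            continue
        try:
            a, f = line.split(",")
            angles.append(float(a))
            factors.append(float(f))
        except ValueError as exc:
            raise ValueError(f"line {ln}: malformed table row {line!r}") from exc
    if not seen_header or not angles:
        raise ValueError("file is not a correction-table CSV")
    return CorrectionTable(np.asarray(angles), np.asarray(factors),
                           sad=sad, metadata=metadata)


# --------------------------------------------------- labeled 3D-grid masks

def write_structure_masks(structures: StructureSet, path) -> None:
    """Write a structure set as a run-length-encoded labeled 3D-grid text
    file.

    Header lines carry the grid geometry; each structure is one line of
    ``name: start+len start+len ...`` runs over the C-order-flattened mask.
    Lossless for boolean masks on the stated grid.
    """
    g = structures.grid
    lines = [
        "# structure-masks v1",
        f"# shape: {g.shape[0]} {g.shape[1]} {g.shape[2]}",
        f"# spacing_mm: {g.spacing[0]:.10g} {g.spacing[1]:.10g} {g.spacing[2]:.10g}",
        f"# origin_mm: {g.origin[0]:.10g} {g.origin[1]:.10g} {g.origin[2]:.10g}",
        f"# frame: {g.frame}",
    ]
    for name, mask in structures.masks.items():
        flat = mask.ravel()
        # run starts: transitions into True
        padded = np.concatenate([[False], flat, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        runs = " ".join(f"{s}+{e - s}" for s, e in zip(starts, ends))
        lines.append(f"{name}: {runs}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure_masks(path) -> StructureSet:
    """Inverse of :func:`write_structure_masks`; the returned StructureSet
    carries an empty (all-zero) DoseGrid with the stored geometry."""
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    body = []
    for line in text:
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                header[k.strip()] = v.strip()
        elif line.strip():
            body.append(line)
    try:
        shape = tuple(int(v) for v in header["shape"].split())
        spacing = tuple(float(v) for v in header["spacing_mm"].split())
        origin = tuple(float(v) for v in header["origin_mm"].split())
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed structure-masks header: {exc}") from exc
    grid = DoseGrid(np.zeros(shape), spacing, origin, header.get("frame", ""))
    n = int(np.prod(shape))
    masks: dict[str, np.ndarray] = {}
    empty: list[str] = []
    for line in body:
        name, _, runs = line.partition(":")
        name = name.strip()
        flat = np.zeros(n, dtype=bool)
        for tok in runs.split():
            s, _, ln = tok.partition("+")
            s, ln = int(s), int(ln)
            if s < 0 or s + ln > n:
                raise ValueError(f"structure {name!r}: run {tok} out of range")
            flat[s:s + ln] = True
        if not flat.any():
            empty.append(name)
        masks[name] = flat.reshape(shape)
    return StructureSet(masks, grid, empty_structures=empty)
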