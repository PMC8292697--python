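"""Read and write the DICOM-RT triplet (RTSTRUCT, RTDOSE, RTPLAN).

All geometry lives in the DICOM patient coordinate system, in millimetres,
as floats. Voxel indices never leave the DVH engine. Only axial, non-tilted
dose grids (identity direction cosines) are supported; anything else raises
:class:`~rtqa.errors.UnsupportedOrientationError`.

The writers exist so that synthetic phantoms and dose fields can round-trip
through genuine DICOM files, which is how the readers are tested.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import (
    FormatError,
    MalformedContourError,
    MalformedDoseError,
    RtqaError,
    UnsupportedOrientationError,
)

RTSTRUCT_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTPLAN_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"

_IDENTITY_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """A named set of closed planar contours in patient coordinates (mm).

    Each contour is an (n, 3) float array of (x, y, z) points with n >= 3 and
    constant z. ``meta`` carries generator-attached facts such as the analytic
    volume of a phantom; ``nonstandard`` marks names left unmapped after
    nomenclature standardization.
    """

    name: str
    roi_number: int
    contours: list = field(default_factory=list)
    color: Optional[tuple] = None
    meta: dict = field(default_factory=dict)
    nonstandard: bool = False

    def validate(self) -> None:
        for i, c in enumerate(self.contours):
            arr = np.asarray(c, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 3:
                raise MalformedContourError(
                    self.roi_number, f"contour {i} is not an (n>=3, 3) point list"
                )
            if not np.allclose(arr[:, 2], arr[0, 2], atol=1e-6):
                raise MalformedContourError(
                    self.roi_number, f"contour {i} has non-constant z"
                )


@dataclass
class StructureSet:
    structures: list = field(default_factory=list)
    frame_of_reference: str = ""
    patient_id: str = ""

    def validate(self) -> None:
        numbers = [s.roi_number for s in self.structures]
        if len(numbers) != len(set(numbers)):
            raise RtqaError("roi_number values are not unique within the set")
        for s in self.structures:
            s.validate()

    def names(self) -> list:
        return [s.name for s in self.structures]

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.structures)


class DoseUnits:
    GY = "GY"
    RELATIVE = "RELATIVE"


@dataclass
class DoseGrid:
    """Regular 3-D scalar dose field in Gy.

    ``origin`` is the (x, y, z) of the first voxel *center*; ``spacing`` is
    (dx, dy) in mm; ``z_offsets`` are per-plane offsets from origin.z, strictly
    increasing; ``values`` has shape (nz, ny, nx).
    """

    origin: tuple
    spacing: tuple
    z_offsets: np.ndarray
    values: np.ndarray
    dose_units: str = DoseUnits.GY
    frame_of_reference: str = ""

    def __post_init__(self):
        self.z_offsets = np.asarray(self.z_offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        nz = len(self.z_offsets)
        if nz == 0:
            raise MalformedDoseError("empty frame-offset vector")
        if nz > 1 and not np.all(np.diff(self.z_offsets) > 0):
            raise MalformedDoseError(
                f"z_offsets not strictly increasing: {self.z_offsets.tolist()}"
            )
        if self.values.ndim != 3 or self.values.shape[0] != nz:
            raise MalformedDoseError(
                f"values shape {self.values.shape} inconsistent with "
                f"{nz} z planes"
            )
        if np.any(self.values < 0):
            raise MalformedDoseError("negative dose values present")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.shape[2])

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.shape[1])

    def z_centers(self) -> np.ndarray:
        return self.origin[2] + self.z_offsets


@dataclass
class PlanSummary:
    prescription_dose: Optional[float] = None  # Gy
    fractions: Optional[int] = None
    target_name: Optional[str] = None
    technique: Optional[str] = None
    plan_label: Optional[str] = None
    warnings: list = field(default_factory=list)

    @property
    def dose_per_fraction(self) -> Optional[float]:
        if self.prescription_dose is None or not self.fractions:
            return None
        return self.prescription_dose / self.fractions

    def validate(self) -> None:
        if self.prescription_dose is not None and self.prescription_dose <= 0:
            raise RtqaError("prescription_dose must be > 0")
        if self.fractions is not None and self.fractions < 1:
            raise RtqaError("fractions must be >= 1")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _check_class(ds: pydicom.Dataset, expected: str, path: str) -> None:
    found = str(getattr(ds, "SOPClassUID", ""))
    if found != expected:
        raise FormatError(expected, found or "<missing>", path)


def read_structure_set(path) -> StructureSet:
    """Read an RT Structure Set file into a :class:`StructureSet`.

    Raises :class:`FormatError` on the wrong storage class and
    :class:`MalformedContourError` when a contour's coordinate count is not a
    multiple of three. Never silently drops a ROI: every entry of the ROI
    sequence appears in the output.
    """
    ds = pydicom.dcmread(str(path))
    _check_class(ds, RTSTRUCT_CLASS, str(path))

    names = {}
    for roi in ds.get("StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName)

    frame = ""
    for ref in ds.get("ReferencedFrameOfReferenceSequence", []):
        frame = str(ref.FrameOfReferenceUID)
        break
    if not frame and ds.get("StructureSetROISequence"):
        frame = str(
            ds.StructureSetROISequence[0].get("ReferencedFrameOfReferenceUID", "")
        )

    structures = []
    seen = set()
    for rc in ds.get("ROIContourSequence", []):
        roi_number = int(rc.ReferencedROINumber)
        seen.add(roi_number)
        color = None
        if "ROIDisplayColor" in rc:
            color = tuple(int(v) for v in rc.ROIDisplayColor)
        contours = []
        for item in rc.get("ContourSequence", []):
            data = [float(v) for v in item.ContourData]
            if len(data) % 3 != 0:
                raise MalformedContourError(
                    roi_number,
                    f"contour coordinate count {len(data)} is not a multiple of 3",
                )
            pts = np.asarray(data, dtype=float).reshape(-1, 3)
            contours.append(pts)
        structures.append(
            Structure(
                name=names.get(roi_number, f"ROI_{roi_number}"),
                roi_number=roi_number,
                contours=contours,
                color=color,
            )
        )
    # ROIs declared but without a contour sequence entry still surface
    for roi_number, name in names.items():
        if roi_number not in seen:
            structures.append(Structure(name=name, roi_number=roi_number))

    ss = StructureSet(
        structures=sorted(structures, key=lambda s: s.roi_number),
        frame_of_reference=frame,
        patient_id=str(ds.get("PatientID", "")),
    )
    ss.validate()
    return ss


def read_dose_grid(path, prescription_dose: Optional[float] = None) -> DoseGrid:
    """Read an RT Dose file into a :class:`DoseGrid` (values in Gy).

    Stored integers are multiplied by DoseGridScaling. RELATIVE dose (percent
    of prescription) is converted to Gy using ``prescription_dose``; without
    it, RELATIVE input raises :class:`MalformedDoseError`.
    """
    ds = pydicom.dcmread(str(path))
    _check_class(ds, RTDOSE_CLASS, str(path))

    orientation = tuple(float(v) for v in ds.get("ImageOrientationPatient", []))
    if orientation and orientation != _IDENTITY_ORIENTATION:
        raise UnsupportedOrientationError(
            f"non-axial orientation {orientation} is not supported"
        )

    if "GridFrameOffsetVector" not in ds:
        raise MalformedDoseError("missing frame-offset vector (GridFrameOffsetVector)")
    offsets = np.atleast_1d(np.asarray(ds.GridFrameOffsetVector, dtype=float))
    if len(offsets) > 1 and not np.all(np.diff(offsets) > 0):
        raise MalformedDoseError(
            f"frame offsets not strictly increasing: {offsets.tolist()}"
        )

    scaling = float(ds.get("DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scaling
    if values.ndim == 2:
        values = values[np.newaxis, :, :]

    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    # PixelSpacing is (row spacing, column spacing) = (dy, dx)
    dy, dx = (float(v) for v in ds.PixelSpacing)

    units = str(ds.get("DoseUnits", "GY")).upper()
    if units == DoseUnits.RELATIVE:
        if prescription_dose is None:
            raise MalformedDoseError(
                "RELATIVE dose units require a prescription dose for conversion"
            )
        values = values / 100.0 * prescription_dose
        units = DoseUnits.GY

    return DoseGrid(
        origin=origin,
        spacing=(dx, dy),
        z_offsets=offsets,
        values=values,
        dose_units=units,
        frame_of_reference=str(ds.get("FrameOfReferenceUID", "")),
    )


def read_plan(path) -> PlanSummary:
    """Read an RT Plan file into a :class:`PlanSummary`.

    A plan from which no prescription dose is derivable returns a summary with
    ``prescription_dose=None`` and a recorded warning rather than raising.
    """
    ds = pydicom.dcmread(str(path))
    _check_class(ds, RTPLAN_CLASS, str(path))

    summary = PlanSummary(plan_label=str(ds.get("RTPlanLabel", "")) or None)

    dose = None
    target = None
    for ref in ds.get("DoseReferenceSequence", []):
        if "TargetPrescriptionDose" in ref:
            dose = float(ref.TargetPrescriptionDose)
            target = str(ref.get("DoseReferenceDescription", "")) or None
            break
    if dose is None:
        summary.warnings.append("no prescription dose derivable from plan")
    summary.prescription_dose = dose
    summary.target_name = target

    fractions = None
    for fg in ds.get("FractionGroupSequence", []):
        if "NumberOfFractionsPlanned" in fg:
            fractions = int(fg.NumberOfFractionsPlanned)
            break
    if fractions is None:
        summary.warnings.append("no fraction count derivable from plan")
    summary.fractions = fractions

    technique = None
    for beam in ds.get("BeamSequence", []):
        if "BeamType" in beam:
            technique = str(beam.BeamType)
            break
    summary.technique = technique
    summary.validate()
    return summary


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _base_dataset(sop_class: str, patient_id: str, frame: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = patient_id or "SYNTH"
    ds.PatientName = "Synthetic^Phantom"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = frame or generate_uid()
    now = datetime.datetime(2020, 1, 1)
    ds.StudyDate = now.strftime("%Y%m%d")
    ds.StudyTime = now.strftime("%H%M%S")
    ds.Modality = {
        RTSTRUCT_CLASS: "RTSTRUCT",
        RTDOSE_CLASS: "RTDOSE",
        RTPLAN_CLASS: "RTPLAN",
    }[sop_class]
    return ds


def write_structure_set(ss: StructureSet, path) -> None:
    ss.validate()
    ds = _base_dataset(RTSTRUCT_CLASS, ss.patient_id, ss.frame_of_reference)
    ds.StructureSetLabel = "rtqa"

    ref = Dataset()
    ref.FrameOfReferenceUID = ds.FrameOfReferenceUID
    ds.ReferencedFrameOfReferenceSequence = [ref]

    roi_seq = []
    contour_seq = []
    for s in ss.structures:
        roi = Dataset()
        roi.ROINumber = s.roi_number
        roi.ROIName = s.name
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = s.roi_number
        if s.color is not None:
            rc.ROIDisplayColor = list(s.color)
        items = []
        for pts in s.contours:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            arr = np.asarray(pts, dtype=float)
            item.NumberOfContourPoints = arr.shape[0]
            item.ContourData = [float(v) for v in arr.ravel()]
            items.append(item)
        rc.ContourSequence = items
        contour_seq.append(rc)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(str(path), enforce_file_format=True)


def write_dose_grid(grid: DoseGrid, path, scaling: float = 1e-4) -> None:
    """Write a :class:`DoseGrid` as an RT Dose file.

    Values are stored as 32-bit unsigned integers under ``scaling`` Gy per
    unit (default 1e-4, i.e. 0.1 mGy resolution).
    """
    grid.validate()
    ds = _base_dataset(RTDOSE_CLASS, "SYNTH", grid.frame_of_reference)
    nz, ny, nx = grid.shape
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = list(_IDENTITY_ORIENTATION)
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]  # dy, dx
    ds.GridFrameOffsetVector = [float(v) for v in grid.z_offsets]
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = grid.dose_units
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = float(scaling)
    stored = np.round(grid.values / scaling).astype(np.uint32)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_plan(plan: PlanSummary, path, frame_of_reference: str = "") -> None:
    plan.validate()
    ds = _base_dataset(RTPLAN_CLASS, "SYNTH", frame_of_reference)
    ds.RTPlanLabel = plan.plan_label or "rtqa-plan"
    ds.RTPlanGeometry = "TREATMENT_DEVICE"
    if plan.prescription_dose is not None:
        ref = Dataset()
        ref.DoseReferenceNumber = 1
        ref.DoseReferenceStructureType = "SITE"
        ref.DoseReferenceType = "TARGET"
        if plan.target_name:
            ref.DoseReferenceDescription = plan.target_name
        ref.TargetPrescriptionDose = float(plan.prescription_dose)
        ds.DoseReferenceSequence = [ref]
    if plan.fractions is not None:
        fg = Dataset()
        fg.FractionGroupNumber = 1
        fg.NumberOfFractionsPlanned = int(plan.fractions)
        fg.NumberOfBeams = 0
        fg.NumberOfBrachyApplicationSetups = 0
        ds.FractionGroupSequence = [fg]
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Case bundle (JSON serialization of the internal model)
# ---------------------------------------------------------------------------

def case_to_dict(ss: StructureSet, grid: Optional[DoseGrid] = None,
                 plan: Optional[PlanSummary] = None) -> dict:
    """Serialize a case (structures + dose + plan) to a JSON-able dict."""
    out = {
        "patient_id": ss.patient_id,
        "frame_of_reference": ss.frame_of_reference,
        "structures": [
            {
                "name": s.name,
                "roi_number": s.roi_number,
                "contours": [np.asarray(c).tolist() for c in s.contours],
                "color": list(s.color) if s.color else None,
                "nonstandard": s.nonstandard,
            }
            for s in ss.structures
        ],
    }
    if grid is not None:
        out["dose"] = {
            "origin": list(grid.origin),
            "spacing": list(grid.spacing),
            "z_offsets": grid.z_offsets.tolist(),
            "shape": list(grid.shape),
            "values": grid.values.ravel().tolist(),
            "dose_units": grid.dose_units,
            "frame_of_reference": grid.frame_of_reference,
        }
    if plan is not None:
        out["plan"] = {
            k: v for k, v in dataclasses.asdict(plan).items()
        }
    return out


def case_from_dict(doc: dict):
    """Inverse of :func:`case_to_dict` -> (StructureSet, DoseGrid|None, PlanSummary|None)."""
    ss = StructureSet(
        structures=[
            Structure(
                name=s["name"],
                roi_number=s["roi_number"],
                contours=[np.asarray(c, dtype=float) for c in s["contours"]],
                color=tuple(s["color"]) if s.get("color") else None,
                nonstandard=bool(s.get("nonstandard", False)),
            )
            for s in doc["structures"]
        ],
        frame_of_reference=doc.get("frame_of_reference", ""),
        patient_id=doc.get("patient_id", ""),
    )
    grid = None
    if "dose" in doc:
        d = doc["dose"]
        grid = DoseGrid(
            origin=tuple(d["origin"]),
            spacing=tuple(d["spacing"]),
            z_offsets=np.asarray(d["z_offsets"]),
            values=np.asarray(d["values"]).reshape(d["shape"]),
            dose_units=d.get("dose_units", DoseUnits.GY),
            frame_of_reference=d.get("frame_of_reference", ""),
        )
    plan = None
    if "plan" in doc:
        plan = PlanSummary(**doc["plan"])
    return ss, grid, plan
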