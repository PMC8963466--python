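"""Domain types and DICOM I/O for RT Plan / RT Dose with explicit dialect tagging.

Two vendor dialects of the DICOM RT Plan are modeled:

* ``monaco`` — the native export of the Unity MR-Linac planning system:
  source-to-axis distance (SAD) 143.5 cm, collimator fixed at 0 degrees, MLC
  leaf positions stored under beam-limiting-device type ``MLCY``, no moving
  X jaws, and a fixed 22-cm superior-inferior field extent (leaf overtravel
  limited to +/- 11 cm).
* ``eclipse`` — the conventional-TPS dialect: SAD 100 cm, collimator 90
  degrees, leaf positions under ``MLCX``, explicit asymmetric X and Y jaws.

All lengths are held internally in **cm at the isocenter-projection plane of
the owning dialect**; DICOM millimetres are converted at the I/O boundary.
Patient-frame vectors (isocenter, reference point, dose-grid geometry) stay
in DICOM millimetres.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "Dialect",
    "Technique",
    "ApertureGeometry",
    "ControlPointRecord",
    "BeamRecord",
    "PlanRecord",
    "DoseGrid",
    "ValidationReport",
    "read_rtplan",
    "write_rtplan",
    "read_rtdose",
    "write_rtdose",
    "validate_plan",
    "LEAF_CLOSURE_TOL_CM",
]

#: Gap (cm, at the dialect's definition plane) at or below which a leaf pair
#: is considered closed/parked.  Single source of truth shared with
#: plan_convert and aperture_ciao.
LEAF_CLOSURE_TOL_CM = 0.05

_RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_UID_ROOT = "1.2.826.0.1.3680043.10.1437."


class Dialect(str, enum.Enum):
    MONACO = "monaco"
    ECLIPSE = "eclipse"


class Technique(str, enum.Enum):
    SAD = "sad"
    EXTENDED_SSD = "extended_ssd"


class DialectError(ValueError):
    """Plan dialect could not be determined or is internally inconsistent."""


class PlanParseError(ValueError):
    """A DICOM RT Plan / RT Dose file violates the modeled conventions."""


@dataclass(frozen=True)
class ApertureGeometry:
    """Static MLC geometry at the owning dialect's definition plane.

    ``leaf_boundaries`` are the n+1 leaf-edge positions (cm) along the
    stacking axis (perpendicular to leaf travel); ``max_half_field`` bounds
    leaf travel (cm), +/- 11 cm at the 143.5-cm plane on Unity.
    """

    n_leaf_pairs: int
    leaf_boundaries: np.ndarray
    max_half_field: float = 11.0

    def __post_init__(self):
        bounds = np.asarray(self.leaf_boundaries, dtype=float)
        object.__setattr__(self, "leaf_boundaries", bounds)
        if bounds.size != self.n_leaf_pairs + 1:
            raise ValueError("leaf_boundaries must have n_leaf_pairs + 1 edges")
        if not np.all(np.diff(bounds) > 0):
            raise ValueError("leaf_boundaries must be strictly increasing")

    @classmethod
    def unity(cls) -> "ApertureGeometry":
        # 31 pairs of 7-mm projected leaves, centered: 21.7 cm stacking span.
        edges = (np.arange(32) - 15.5) * 0.7
        return cls(n_leaf_pairs=31, leaf_boundaries=edges, max_half_field=11.0)

    @property
    def span(self) -> float:
        return float(self.leaf_boundaries[-1] - self.leaf_boundaries[0])

    def scaled(self, factor: float) -> "ApertureGeometry":
        return ApertureGeometry(
            n_leaf_pairs=self.n_leaf_pairs,
            leaf_boundaries=self.leaf_boundaries * factor,
            max_half_field=self.max_half_field * factor,
        )


@dataclass
class ControlPointRecord:
    """One aperture segment with its fraction of the beam meterset.

    Leaf positions are cm along the leaf-travel axis at the dialect's
    definition plane; ``bank_a[i] <= bank_b[i]`` for every pair.  ``jaw_x``
    (travel axis) is absent in the monaco dialect; ``jaw_y`` is the fixed
    +/- 11 cm superior-inferior extent there.
    """

    mu_weight: float
    leaf_bank_a: np.ndarray
    leaf_bank_b: np.ndarray
    jaw_x: tuple[float, float] | None
    jaw_y: tuple[float, float]

    def __post_init__(self):
        self.leaf_bank_a = np.asarray(self.leaf_bank_a, dtype=float)
        self.leaf_bank_b = np.asarray(self.leaf_bank_b, dtype=float)

    def open_pairs(self, tol: float = LEAF_CLOSURE_TOL_CM) -> np.ndarray:
        """Boolean mask of leaf pairs with gap strictly above the closure tolerance."""
        return (self.leaf_bank_b - self.leaf_bank_a) > tol

    def travel_window(self) -> tuple[float, float]:
        """Field limit along the leaf-travel axis (jaw_x if present, else the
        fixed superior-inferior jaw)."""
        return self.jaw_x if self.jaw_x is not None else self.jaw_y

    def stack_window(self) -> tuple[float, float] | None:
        """Field limit along the stacking axis (Y jaws in the eclipse dialect,
        none beyond the leaf boundaries in monaco)."""
        return self.jaw_y if self.jaw_x is not None else None


@dataclass
class BeamRecord:
    dialect: Dialect
    beam_number: int
    name: str
    gantry_angle: float
    collimator_angle: float
    sad: float  # nominal SAD, cm (143.5 monaco / 100.0 eclipse)
    source_distance: float  # physical source-to-isocenter distance, cm
    technique: Technique
    energy_label: str
    mu: float
    control_points: list[ControlPointRecord]
    isocenter: np.ndarray  # mm, patient frame
    geometry: ApertureGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.isocenter = np.asarray(self.isocenter, dtype=float)


@dataclass
class PlanRecord:
    dialect: Dialect
    beams: list[BeamRecord]
    reference_point: np.ndarray  # mm, patient frame
    machine_label: str = "UnityQA"
    fraction_label: str = "fx"

    def __post_init__(self):
        self.reference_point = np.asarray(self.reference_point, dtype=float)

    def beam_by_number(self, number: int) -> BeamRecord:
        for b in self.beams:
            if b.beam_number == number:
                return b
        raise KeyError(f"no beam numbered {number}")


@dataclass
class DoseGrid:
    """3D dose array in Gy with axis order ``values[iz, iy, ix]``.

    ``origin`` is the patient-frame position (mm) of voxel (0, 0, 0);
    ``orientation`` columns are the patient-frame directions of the x-, y-
    and z-index axes (identity for the axis-aligned grids written here).
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray  # (dx, dy, dz) mm
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    summation: str = "beam"
    source_engine: str = ""
    beam_number: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3), atol=1e-6):
            raise ValueError("orientation must be orthonormal")


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, msg: str) -> None:
        self.issues.append(msg)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_DIALECT_TRIPLE = {
    Dialect.MONACO: (143.5, 0.0, "7MV-FFF"),
    Dialect.ECLIPSE: (100.0, 90.0, "6MV-FFF"),
}


def validate_plan(plan: PlanRecord) -> ValidationReport:
    """Report every violated invariant with beam / control-point indices."""
    rep = ValidationReport()
    if not plan.beams:
        rep.add("plan has no beams")
        return rep
    if not np.all(np.isfinite(plan.reference_point)):
        rep.add("reference_point is not finite")
    sad_exp, coll_exp, energy_exp = _DIALECT_TRIPLE[plan.dialect]
    for bi, beam in enumerate(plan.beams):
        tag = f"beam[{bi}] ({beam.name})"
        if beam.dialect != plan.dialect:
            rep.add(f"{tag}: dialect {beam.dialect.value} != plan {plan.dialect.value}")
        if not 0 <= beam.gantry_angle < 360:
            rep.add(f"{tag}: gantry angle {beam.gantry_angle} outside [0, 360)")
        if beam.mu < 0:
            rep.add(f"{tag}: negative MU")
        if not beam.control_points:
            rep.add(f"{tag}: no control points")
            continue
        if abs(beam.sad - sad_exp) > 1e-6:
            rep.add(f"{tag}: SAD {beam.sad} inconsistent with {plan.dialect.value} dialect")
        if abs(beam.collimator_angle - coll_exp) > 1e-6:
            rep.add(f"{tag}: collimator {beam.collimator_angle} inconsistent with dialect")
        if beam.energy_label != energy_exp:
            rep.add(f"{tag}: energy label {beam.energy_label!r} inconsistent with dialect")
        total = 0.0
        for ci, cp in enumerate(beam.control_points):
            bad = np.nonzero(cp.leaf_bank_a > cp.leaf_bank_b + 1e-9)[0]
            for leaf in bad:
                rep.add(f"{tag} cp[{ci}]: bank_a[{leaf}] > bank_b[{leaf}]")
            if cp.leaf_bank_a.size != beam.geometry.n_leaf_pairs:
                rep.add(f"{tag} cp[{ci}]: leaf count != geometry n_leaf_pairs")
            if cp.mu_weight < -1e-12:
                rep.add(f"{tag} cp[{ci}]: negative mu_weight")
            total += cp.mu_weight
            if plan.dialect == Dialect.MONACO:
                if cp.jaw_x is not None:
                    rep.add(f"{tag} cp[{ci}]: monaco dialect must not carry X jaws")
                lo, hi = cp.jaw_y
                if abs((hi - lo) - 22.0) > 1e-6:
                    rep.add(f"{tag} cp[{ci}]: monaco jaw_y extent {hi - lo:.3f} != 22 cm")
            else:
                if cp.jaw_x is None:
                    rep.add(f"{tag} cp[{ci}]: eclipse dialect requires X jaws")
        if abs(total - 1.0) > 1e-6:
            rep.add(f"{tag}: control point weights sum to {total:.6f}, expected 1")
    return rep


# ---------------------------------------------------------------------------
# RT Plan I/O
# ---------------------------------------------------------------------------


def _file_meta(sop_class: str, sop_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _det_uid(*parts) -> str:
    """Deterministic UID so identical content yields identical bytes."""
    return generate_uid(prefix=_UID_ROOT, entropy_srcs=[str(p) for p in parts])


def _energy_to_label(energy: float, fff: bool) -> str:
    return f"{int(round(energy))}MV" + ("-FFF" if fff else "")


def _label_to_energy(label: str) -> tuple[float, bool]:
    head = label.split("MV")[0]
    return float(head), label.endswith("FFF")


def write_rtplan(plan: PlanRecord, path) -> None:
    """Emit a dialect-correct DICOM RT Plan (MLCX vs MLCY, jaw sequences).

    Refuses to write a plan that fails :func:`validate_plan`.
    """
    rep = validate_plan(plan)
    if not rep.ok:
        raise PlanParseError("refusing to write invalid plan: " + "; ".join(rep.issues))

    sop_uid = _det_uid("rtplan", plan.fraction_label, plan.machine_label, len(plan.beams))
    ds = FileDataset(str(path), {}, file_meta=_file_meta(_RTPLAN_SOP, sop_uid), preamble=b"\0" * 128)
    ds.SOPClassUID = _RTPLAN_SOP
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTPLAN"
    ds.PatientName = "QA^Synthetic"
    ds.PatientID = "IMUCHECK"
    ds.StudyInstanceUID = _det_uid("study", plan.fraction_label)
    ds.SeriesInstanceUID = _det_uid("series", plan.fraction_label)
    ds.RTPlanLabel = plan.fraction_label
    ds.RTPlanGeometry = "PATIENT"

    dref = Dataset()
    dref.DoseReferenceNumber = 1
    dref.DoseReferenceStructureType = "POINT"
    dref.DoseReferenceType = "TARGET"
    dref.DoseReferencePointCoordinates = [float(v) for v in plan.reference_point]
    ds.DoseReferenceSequence = [dref]

    mlc_tag = "MLCY" if plan.dialect == Dialect.MONACO else "MLCX"

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(plan.beams)
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for beam in plan.beams:
        rb = Dataset()
        rb.ReferencedBeamNumber = beam.beam_number
        rb.BeamMeterset = float(beam.mu)
        fg.ReferencedBeamSequence.append(rb)

        b = Dataset()
        b.BeamNumber = beam.beam_number
        b.BeamName = beam.name
        b.BeamDescription = (
            f"TECHNIQUE:{beam.technique.value};SRCDIST:{beam.source_distance:.4f}"
        )
        b.TreatmentMachineName = plan.machine_label
        b.RadiationType = "PHOTON"
        b.BeamType = "STATIC"
        b.TreatmentDeliveryType = "TREATMENT"
        b.SourceAxisDistance = beam.sad * 10.0
        b.NumberOfWedges = 0
        b.NumberOfCompensators = 0
        b.NumberOfBoli = 0
        b.NumberOfBlocks = 0
        b.FinalCumulativeMetersetWeight = 1.0

        energy, fff = _label_to_energy(beam.energy_label)
        if fff:
            fm = Dataset()
            fm.FluenceMode = "NON_STANDARD"
            fm.FluenceModeID = "FFF"
            b.PrimaryFluenceModeSequence = [fm]

        # machine-level beam limiting devices
        bld_seq = []
        if plan.dialect == Dialect.ECLIPSE:
            for jtype in ("ASYMX", "ASYMY"):
                j = Dataset()
                j.RTBeamLimitingDeviceType = jtype
                j.NumberOfLeafJawPairs = 1
                bld_seq.append(j)
        mlc = Dataset()
        mlc.RTBeamLimitingDeviceType = mlc_tag
        mlc.NumberOfLeafJawPairs = beam.geometry.n_leaf_pairs
        mlc.LeafPositionBoundaries = [float(v) * 10.0 for v in beam.geometry.leaf_boundaries]
        bld_seq.append(mlc)
        b.BeamLimitingDeviceSequence = bld_seq

        # control points: one per segment plus a terminal CP repeating the
        # last aperture at cumulative weight 1.
        cps = beam.control_points
        cum = np.concatenate([[0.0], np.cumsum([cp.mu_weight for cp in cps])])
        cp_seq = []
        n_emit = len(cps) + 1
        for ci in range(n_emit):
            src = cps[min(ci, len(cps) - 1)]
            c = Dataset()
            c.ControlPointIndex = ci
            c.CumulativeMetersetWeight = float(min(cum[ci], 1.0))
            if ci == 0:
                c.GantryAngle = beam.gantry_angle
                c.GantryRotationDirection = "NONE"
                c.BeamLimitingDeviceAngle = beam.collimator_angle
                c.BeamLimitingDeviceRotationDirection = "NONE"
                c.PatientSupportAngle = 0.0
                c.PatientSupportRotationDirection = "NONE"
                c.IsocenterPosition = [float(v) for v in beam.isocenter]
                c.NominalBeamEnergy = energy
            pos_seq = []
            if src.jaw_x is not None:
                jx = Dataset()
                jx.RTBeamLimitingDeviceType = "ASYMX"
                jx.LeafJawPositions = [src.jaw_x[0] * 10.0, src.jaw_x[1] * 10.0]
                pos_seq.append(jx)
                jy = Dataset()
                jy.RTBeamLimitingDeviceType = "ASYMY"
                jy.LeafJawPositions = [src.jaw_y[0] * 10.0, src.jaw_y[1] * 10.0]
                pos_seq.append(jy)
            m = Dataset()
            m.RTBeamLimitingDeviceType = mlc_tag
            m.LeafJawPositions = [float(v) * 10.0 for v in src.leaf_bank_a] + [
                float(v) * 10.0 for v in src.leaf_bank_b
            ]
            pos_seq.append(m)
            c.BeamLimitingDevicePositionSequence = pos_seq
            cp_seq.append(c)
        b.NumberOfControlPoints = n_emit
        b.ControlPointSequence = cp_seq
        ds.BeamSequence.append(b)

    ds.save_as(str(path), enforce_file_format=True)


def _parse_description(desc: str) -> tuple[Technique, float | None]:
    technique, srcdist = Technique.SAD, None
    for part in (desc or "").split(";"):
        if part.startswith("TECHNIQUE:"):
            technique = Technique(part.split(":", 1)[1].lower())
        elif part.startswith("SRCDIST:"):
            srcdist = float(part.split(":", 1)[1])
    return technique, srcdist


def read_rtplan(path) -> PlanRecord:
    """Read a DICOM RT Plan; auto-detect dialect from the MLC tag and SAD.

    Dialect detection precedence: MLC device-type name first (``MLCY`` vs
    ``MLCX``), SAD as confirmation.  Disagreement or anything else raises
    :class:`DialectError` — never a silent guess.
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTPLAN":
        raise PlanParseError(f"{path}: not an RT Plan (Modality={getattr(ds, 'Modality', '?')})")

    ref_point = np.zeros(3)
    for dref in getattr(ds, "DoseReferenceSequence", []):
        if hasattr(dref, "DoseReferencePointCoordinates"):
            ref_point = np.asarray([float(v) for v in dref.DoseReferencePointCoordinates])
            break

    mu_by_number: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            mu_by_number[int(rb.ReferencedBeamNumber)] = float(getattr(rb, "BeamMeterset", 0.0))

    beams: list[BeamRecord] = []
    dialect: Dialect | None = None
    for b in ds.BeamSequence:
        name = str(getattr(b, "BeamName", f"beam{b.BeamNumber}"))
        mlc_types = {
            d.RTBeamLimitingDeviceType
            for d in getattr(b, "BeamLimitingDeviceSequence", [])
            if d.RTBeamLimitingDeviceType in ("MLCX", "MLCY")
        }
        if not mlc_types:
            raise PlanParseError(f"beam {name}: missing MLC beam-limiting-device sequence")
        if len(mlc_types) > 1:
            raise DialectError(f"beam {name}: both MLCX and MLCY present")
        mlc_tag = mlc_types.pop()
        beam_dialect = Dialect.MONACO if mlc_tag == "MLCY" else Dialect.ECLIPSE
        sad_cm = float(b.SourceAxisDistance) / 10.0
        sad_expected = _DIALECT_TRIPLE[beam_dialect][0]
        if abs(sad_cm - sad_expected) > 0.1:
            raise DialectError(
                f"beam {name}: MLC tag {mlc_tag} implies {beam_dialect.value} "
                f"(SAD {sad_expected} cm) but file says SAD {sad_cm} cm"
            )
        if dialect is None:
            dialect = beam_dialect
        elif dialect != beam_dialect:
            raise DialectError("beams disagree on dialect within one plan")

        for d in b.BeamLimitingDeviceSequence:
            if d.RTBeamLimitingDeviceType == mlc_tag:
                boundaries = np.asarray([float(v) for v in d.LeafPositionBoundaries]) / 10.0
                geometry = ApertureGeometry(
                    n_leaf_pairs=int(d.NumberOfLeafJawPairs),
                    leaf_boundaries=boundaries,
                    max_half_field=11.0 if beam_dialect == Dialect.MONACO else 11.0 / 1.435,
                )
                break

        technique, srcdist = _parse_description(getattr(b, "BeamDescription", ""))
        cp0 = b.ControlPointSequence[0]
        gantry = float(getattr(cp0, "GantryAngle", 0.0)) % 360.0
        coll = float(getattr(cp0, "BeamLimitingDeviceAngle", 0.0))
        iso = np.asarray([float(v) for v in getattr(cp0, "IsocenterPosition", (0, 0, 0))])
        energy = float(getattr(cp0, "NominalBeamEnergy", 0.0))
        fff = any(
            getattr(fm, "FluenceModeID", "") == "FFF"
            for fm in getattr(b, "PrimaryFluenceModeSequence", [])
        )
        label = _energy_to_label(energy, fff)

        raw = []
        for c in b.ControlPointSequence:
            jaw_x = jaw_y = None
            leaves = None
            for p in getattr(c, "BeamLimitingDevicePositionSequence", []):
                vals = [float(v) / 10.0 for v in p.LeafJawPositions]
                if p.RTBeamLimitingDeviceType in ("ASYMX", "X"):
                    jaw_x = (vals[0], vals[1])
                elif p.RTBeamLimitingDeviceType in ("ASYMY", "Y"):
                    jaw_y = (vals[0], vals[1])
                elif p.RTBeamLimitingDeviceType == mlc_tag:
                    leaves = np.asarray(vals)
            raw.append((float(c.CumulativeMetersetWeight), jaw_x, jaw_y, leaves))

        n = geometry.n_leaf_pairs
        segments: list[ControlPointRecord] = []
        for i in range(len(raw) - 1):
            cum_i, jaw_x, jaw_y, leaves = raw[i]
            weight = raw[i + 1][0] - cum_i
            if leaves is None:
                raise PlanParseError(f"beam {name}: control point {i} lacks MLC positions")
            if jaw_y is None:
                jaw_y = (-geometry.max_half_field, geometry.max_half_field)
            segments.append(
                ControlPointRecord(
                    mu_weight=weight,
                    leaf_bank_a=leaves[:n],
                    leaf_bank_b=leaves[n:],
                    jaw_x=jaw_x,
                    jaw_y=jaw_y,
                )
            )
        if len(raw) == 1:
            raise PlanParseError(f"beam {name}: needs at least two control points")

        beams.append(
            BeamRecord(
                dialect=beam_dialect,
                beam_number=int(b.BeamNumber),
                name=name,
                gantry_angle=gantry,
                collimator_angle=coll,
                sad=sad_cm,
                source_distance=srcdist if srcdist is not None else sad_cm,
                technique=technique,
                energy_label=label,
                mu=mu_by_number.get(int(b.BeamNumber), 0.0),
                control_points=segments,
                isocenter=iso,
                geometry=geometry,
            )
        )

    if dialect is None:
        raise DialectError("plan contains no beams")
    return PlanRecord(
        dialect=dialect,
        beams=beams,
        reference_point=ref_point,
        machine_label=str(getattr(ds.BeamSequence[0], "TreatmentMachineName", "")),
        fraction_label=str(getattr(ds, "RTPlanLabel", "fx")),
    )


# ---------------------------------------------------------------------------
# RT Dose I/O
# ---------------------------------------------------------------------------


def write_rtdose(grid: DoseGrid, path) -> None:
    """Write a multiframe DICOM RT Dose (uniform GridFrameOffsetVector)."""
    vals = grid.values
    if vals.size == 0:
        raise PlanParseError("refusing to write an empty dose grid")
    vmax = float(vals.max())
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    stored = np.round(vals / scaling).astype(np.uint32)

    sop_uid = _det_uid("rtdose", grid.source_engine, grid.beam_number, vals.shape)
    ds = FileDataset(str(path), {}, file_meta=_file_meta(_RTDOSE_SOP, sop_uid), preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_SOP
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.PatientName = "QA^Synthetic"
    ds.PatientID = "IMUCHECK"
    ds.StudyInstanceUID = _det_uid("study", grid.source_engine)
    ds.SeriesInstanceUID = _det_uid("doseseries", grid.source_engine, grid.beam_number)
    ds.SeriesDescription = grid.source_engine
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = grid.summation.upper()
    ds.DoseGridScaling = scaling
    nz, ny, nx = vals.shape
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]  # row, col
    ds.GridFrameOffsetVector = [float(i * grid.spacing[2]) for i in range(nz)]
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [
        *(float(v) for v in grid.orientation[:, 0]),
        *(float(v) for v in grid.orientation[:, 1]),
    ]
    ds.FrameOfReferenceUID = _det_uid("frame", grid.source_engine)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    if grid.beam_number is not None:
        rp = Dataset()
        rp.ReferencedSOPClassUID = _RTPLAN_SOP
        rp.ReferencedSOPInstanceUID = _det_uid("rtplan-ref", grid.source_engine)
        rfg = Dataset()
        rfg.ReferencedFractionGroupNumber = 1
        rbeam = Dataset()
        rbeam.ReferencedBeamNumber = int(grid.beam_number)
        rfg.ReferencedBeamSequence = [rbeam]
        rp.ReferencedFractionGroupSequence = [rfg]
        ds.ReferencedRTPlanSequence = [rp]
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose into Gy; requires uniform slice spacing and an
    explicit DoseGridScaling."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise PlanParseError(f"{path}: not an RT Dose file")
    if "DoseGridScaling" not in ds:
        raise PlanParseError(f"{path}: missing DoseGridScaling")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if offsets.size < 2:
        raise PlanParseError(f"{path}: dose grid has fewer than 2 frames")
    steps = np.diff(offsets)
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise PlanParseError(f"{path}: non-uniform slice spacing")
    vals = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if vals.size == 0:
        raise PlanParseError(f"{path}: empty dose grid")
    spacing = np.array([float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), float(steps[0])])
    iop = [float(v) for v in ds.ImageOrientationPatient]
    row_dir, col_dir = np.asarray(iop[:3]), np.asarray(iop[3:])
    orient = np.column_stack([row_dir, col_dir, np.cross(row_dir, col_dir)])
    beam_number = None
    for rp in getattr(ds, "ReferencedRTPlanSequence", []):
        for rfg in getattr(rp, "ReferencedFractionGroupSequence", []):
            for rb in getattr(rfg, "ReferencedBeamSequence", []):
                beam_number = int(rb.ReferencedBeamNumber)
    return DoseGrid(
        values=vals,
        origin=np.asarray([float(v) for v in ds.ImagePositionPatient]),
        spacing=spacing,
        orientation=orient,
        summation=str(getattr(ds, "DoseSummationType", "BEAM")).lower(),
        source_engine=str(getattr(ds, "SeriesDescription", "")),
        beam_number=beam_number,
    )
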