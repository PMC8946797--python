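"""Domain model for longitudinal glioblastoma response assessment.

Holds the measurement-level types shared by every stage of the pipeline:
per-lesion bidimensional diameters and segmented volumes, per-scan
aggregated tumor burden, per-patient timelines with clinical anchor dates,
and the trajectory/endpoint records the criteria engines and survival
stages produce.

Conventions
-----------
* diameters in mm, contrast-enhancing (CE) and T2/FLAIR volumes in cm^3,
  T2/FLAIR cross-section area in mm^2;
* a month is 30.4375 days (calendar mean);
* 2D measurability is per lesion (both diameters >= 1 cm), volumetric
  measurability is on the summed total CE volume (>= 1 cm^3);
* dates are ``datetime.date`` (or ``datetime.datetime`` where sub-day
  resolution is needed), consistent within one timeline.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "Arm",
    "VitalStatus",
    "ResponseLabel",
    "Criterion",
    "MeasurabilityCutoffs",
    "LesionMeasurement",
    "ScanRecord",
    "TumorBurden",
    "PatientTimeline",
    "CriterionTrajectory",
    "EndpointRecord",
    "aggregate_burden",
    "months_between",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_frames",
]

#: Mean calendar month length in days.
DAYS_PER_MONTH = 30.4375


class Arm(str, enum.Enum):
    """Treatment arm of the trial: standard of care with or without vaccine."""

    SOC = "SOC"
    SOC_PLUS_VACCINE = "SOC_plus_vaccine"


class VitalStatus(str, enum.Enum):
    DEAD = "dead"
    ALIVE_AT_CLOSURE = "alive_at_closure"
    LOST_TO_FOLLOW_UP = "lost_to_follow_up"


class ResponseLabel(str, enum.Enum):
    """Per-scan response call.

    CR/PR/SD/PD are terminal per-scan outcomes; the preliminary labels are
    emitted by confirmation-based criteria (mRANO, iRANO) and must be
    resolved by a later scan or the end of follow-up. PSP/PSEUDORESPONSE
    mark the adjudication scan of a pseudo-phenomenon.
    """

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    PRELIMINARY_PD = "preliminary_PD"
    PRELIMINARY_PR_OR_CR = "preliminary_PR_or_CR"
    PSP_ADJUDICATED = "PsP_adjudicated"
    PSEUDORESPONSE_ADJUDICATED = "pseudoresponse_adjudicated"


class Criterion(str, enum.Enum):
    MACDONALD = "MacDonald"
    RANO = "RANO"
    VOL_RANO = "Vol-RANO"
    MRANO = "mRANO"
    VOL_MRANO = "Vol-mRANO"
    IRANO = "iRANO"


#: Fixed reporting order for comparison tables.
CRITERION_ORDER = [
    Criterion.MACDONALD,
    Criterion.RANO,
    Criterion.VOL_RANO,
    Criterion.MRANO,
    Criterion.VOL_MRANO,
    Criterion.IRANO,
]


class DataValidationError(ValueError):
    """A measurement or timeline violates the domain invariants."""


@dataclass(frozen=True)
class MeasurabilityCutoffs:
    """Measurable-disease cutoffs.

    min_diameter_mm: both diameters of a lesion must reach this for the
        lesion to count as 2D-measurable (1 cm).
    min_volume_cm3: summed CE volume at/above this counts as
        volumetrically measurable (1 cm^3).
    """

    min_diameter_mm: float = 10.0
    min_volume_cm3: float = 1.0

    def __post_init__(self) -> None:
        if self.min_diameter_mm <= 0 or self.min_volume_cm3 <= 0:
            raise DataValidationError("measurability cutoffs must be positive")


DEFAULT_CUTOFFS = MeasurabilityCutoffs()


@dataclass(frozen=True)
class LesionMeasurement:
    """One enhancing lesion on one scan.

    ``diam_longest`` and ``diam_perp`` are the largest diameter and its
    perpendicular on the same axial slice (mm); their product is the
    lesion's cross-section area contribution. ``ce_volume`` is the
    segmented CE volume (cm^3), optional because 2D-only reads exist.
    """

    lesion_id: str
    diam_longest: float
    diam_perp: float
    ce_volume: Optional[float] = None
    is_new: bool = False

    def __post_init__(self) -> None:
        if self.diam_perp < 0 or self.diam_longest < 0:
            raise DataValidationError(
                f"lesion {self.lesion_id}: negative diameter"
            )
        if self.diam_longest < self.diam_perp:
            raise DataValidationError(
                f"lesion {self.lesion_id}: longest diameter smaller than perpendicular"
            )
        if self.ce_volume is not None and self.ce_volume < 0:
            raise DataValidationError(
                f"lesion {self.lesion_id}: negative volume"
            )

    @property
    def product_2d(self) -> float:
        """Cross-section area: longest diameter x perpendicular diameter (mm^2)."""
        return self.diam_longest * self.diam_perp

    def is_measurable_2d(self, cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS) -> bool:
        return (
            self.diam_longest >= cutoffs.min_diameter_mm
            and self.diam_perp >= cutoffs.min_diameter_mm
        )


@dataclass(frozen=True)
class ScanRecord:
    """One MRI timepoint: enhancing lesions plus T2/FLAIR abnormality load."""

    scan_date: _dt.date
    lesions: tuple[LesionMeasurement, ...] = ()
    t2flair_volume: Optional[float] = None
    t2flair_area: Optional[float] = None
    t2flair_new_lesion: bool = False
    is_post_op: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        for v, name in ((self.t2flair_volume, "t2flair_volume"),
                        (self.t2flair_area, "t2flair_area")):
            if v is not None and v < 0:
                raise DataValidationError(f"negative {name}")


@dataclass(frozen=True)
class TumorBurden:
    """Aggregated disease burden of one scan.

    ``sum_product_2d`` sums diameter products over 2D-measurable lesions
    only (sub-cutoff lesions never contribute); ``total_ce_volume`` sums
    every lesion's volume.
    """

    sum_product_2d: float
    total_ce_volume: float
    t2flair_volume: Optional[float]
    t2flair_area: Optional[float]
    measurable_2d: bool
    measurable_vol: bool
    any_new_lesion: bool
    any_new_measurable_lesion: bool
    has_enhancing_disease: bool
    t2flair_new_lesion: bool = False


@dataclass(frozen=True)
class PatientTimeline:
    """Ordered scans plus the clinical anchor dates of one patient.

    ``diagnosis_date`` is the pre-surgery MRI (origin of PFS and OS);
    response references use the post-op scan, so both dates are kept.
    """

    patient_id: str
    arm: Arm
    diagnosis_date: _dt.date
    scans: tuple[ScanRecord, ...]
    last_contact_date: _dt.date
    vital_status: VitalStatus
    immunotherapy_start: Optional[_dt.date] = None
    reresection_date: Optional[_dt.date] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scans", tuple(self.scans))
        dates = [s.scan_date for s in self.scans]
        if any(d2 <= d1 for d1, d2 in zip(dates, dates[1:])):
            raise DataValidationError(
                f"patient {self.patient_id}: scan dates must strictly increase"
            )
        if dates and min(dates) < self.diagnosis_date:
            raise DataValidationError(
                f"patient {self.patient_id}: scan before diagnosis date"
            )
        if sum(s.is_post_op for s in self.scans) > 1:
            raise DataValidationError(
                f"patient {self.patient_id}: more than one post-op scan"
            )
        if dates and self.last_contact_date < max(dates):
            raise DataValidationError(
                f"patient {self.patient_id}: last contact precedes last scan"
            )

    @property
    def post_op_index(self) -> int:
        """Index of the post-op (baseline) scan; raises if absent."""
        for i, s in enumerate(self.scans):
            if s.is_post_op:
                return i
        raise DataValidationError(
            f"patient {self.patient_id}: no post-op baseline scan"
        )

    @property
    def followup_scans(self) -> tuple[ScanRecord, ...]:
        return self.scans[self.post_op_index + 1:]


@dataclass
class CriterionTrajectory:
    """Per-scan labels and progression summary for one (patient, criterion).

    ``per_scan_labels`` has one entry per follow-up scan (post-baseline).
    ``reference_log`` records, per follow-up scan, which scans served as
    reference baseline and nadir plus the engine state, so every call can
    be audited. ``ce_progression_flags``/``t2_progression_flags`` record
    the raw per-scan firing of the enhancing and T2/FLAIR progression
    rules (used for T2-only detection).
    """

    criterion: Criterion
    patient_id: str
    per_scan_labels: list[ResponseLabel]
    scan_dates: list[_dt.date]
    progression_date: Optional[_dt.date] = None
    progression_event: bool = False
    psp_confirmed: bool = False
    t2_only_progression: bool = False
    t2_lead_months: Optional[float] = None
    reference_log: list[dict] = field(default_factory=list)
    ce_progression_flags: list[bool] = field(default_factory=list)
    t2_progression_flags: list[bool] = field(default_factory=list)


@dataclass(frozen=True)
class EndpointRecord:
    """PFS/OS/PPS times (months) with event indicators for one (patient, criterion)."""

    patient_id: str
    criterion: Criterion
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    pps_months: Optional[float] = None
    pps_event: bool = False

    def __post_init__(self) -> None:
        if self.pfs_months < 0 or self.os_months < 0:
            raise DataValidationError("negative survival time")
        if self.pfs_months > self.os_months + 1e-9:
            raise DataValidationError("PFS exceeds OS")


# ---------------------------------------------------------------------------
# Operations


def months_between(d1: _dt.date, d2: _dt.date) -> float:
    """Elapsed time from ``d1`` to ``d2`` in mean calendar months.

    Accepts dates or datetimes (consistent types). Raises if ``d2 < d1``.
    """
    if d2 < d1:
        raise DataValidationError(f"dates out of order: {d1} > {d2}")
    delta = d2 - d1
    days = delta.total_seconds() / 86400.0
    return days / DAYS_PER_MONTH


def aggregate_burden(
    scan: ScanRecord, cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS
) -> TumorBurden:
    """Aggregate one scan's lesions into a :class:`TumorBurden`.

    The bidimensional sum includes only lesions meeting the per-lesion 2D
    cutoff (both diameters >= 1 cm); the volumetric total sums all lesion
    volumes, and volumetric measurability is judged on that total.
    """
    sum_2d = 0.0
    total_vol = 0.0
    measurable_2d = False
    any_new = False
    any_new_meas = False
    has_ce = False
    for les in scan.lesions:
        if les.diam_longest > 0 or (les.ce_volume or 0.0) > 0:
            has_ce = True
        if les.is_new:
            any_new = True
        meas = les.is_measurable_2d(cutoffs)
        vol_meas = (les.ce_volume or 0.0) >= cutoffs.min_volume_cm3
        if les.is_new and (meas or vol_meas):
            any_new_meas = True
        if meas:
            measurable_2d = True
            sum_2d += les.product_2d
        if les.ce_volume is not None:
            total_vol += les.ce_volume
    return TumorBurden(
        sum_product_2d=sum_2d,
        total_ce_volume=total_vol,
        t2flair_volume=scan.t2flair_volume,
        t2flair_area=scan.t2flair_area,
        measurable_2d=measurable_2d,
        measurable_vol=total_vol >= cutoffs.min_volume_cm3,
        any_new_lesion=any_new,
        any_new_measurable_lesion=any_new_meas,
        has_enhancing_disease=has_ce,
        t2flair_new_lesion=scan.t2flair_new_lesion,
    )


# ---------------------------------------------------------------------------
# CSV interchange
#
# Long-format measurement table: one row per (patient, scan, lesion); scans
# without lesions carry one row with empty lesion fields. Companion
# per-patient table holds the clinical anchors. ISO-8601 dates.

MEASUREMENT_COLUMNS = [
    "patient_id", "arm", "diagnosis_date", "scan_date", "is_post_op",
    "lesion_id", "diam_longest_mm", "diam_perp_mm", "ce_volume_cm3",
    "t2flair_volume_cm3", "t2flair_area_mm2", "new_lesion",
    "t2flair_new_lesion",
]

PATIENT_COLUMNS = [
    "patient_id", "arm", "diagnosis_date", "immunotherapy_start",
    "reresection_date", "last_contact_date", "vital_status",
]


def _parse_date(v) -> Optional[_dt.date]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, (_dt.date, _dt.datetime)):
        return v
    s = str(v)
    try:
        return _dt.datetime.fromisoformat(s) if "T" in s else _dt.date.fromisoformat(s)
    except ValueError as exc:
        raise DataValidationError(f"bad ISO date: {v!r}") from exc


def _opt_float(v) -> Optional[float]:
    if v is None or v == "" or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def cohort_to_frames(
    timelines: Iterable[PatientTimeline],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize timelines to (measurements, patients) DataFrames."""
    mrows, prows = [], []
    for tl in timelines:
        prows.append({
            "patient_id": tl.patient_id,
            "arm": tl.arm.value,
            "diagnosis_date": tl.diagnosis_date.isoformat(),
            "immunotherapy_start": (
                tl.immunotherapy_start.isoformat() if tl.immunotherapy_start else ""
            ),
            "reresection_date": (
                tl.reresection_date.isoformat() if tl.reresection_date else ""
            ),
            "last_contact_date": tl.last_contact_date.isoformat(),
            "vital_status": tl.vital_status.value,
        })
        for scan in tl.scans:
            base = {
                "patient_id": tl.patient_id,
                "arm": tl.arm.value,
                "diagnosis_date": tl.diagnosis_date.isoformat(),
                "scan_date": scan.scan_date.isoformat(),
                "is_post_op": scan.is_post_op,
                "t2flair_volume_cm3": scan.t2flair_volume,
                "t2flair_area_mm2": scan.t2flair_area,
                "t2flair_new_lesion": scan.t2flair_new_lesion,
            }
            if scan.lesions:
                for les in scan.lesions:
                    mrows.append({**base,
                                  "lesion_id": les.lesion_id,
                                  "diam_longest_mm": les.diam_longest,
                                  "diam_perp_mm": les.diam_perp,
                                  "ce_volume_cm3": les.ce_volume,
                                  "new_lesion": les.is_new})
            else:
                mrows.append({**base, "lesion_id": "", "diam_longest_mm": None,
                              "diam_perp_mm": None, "ce_volume_cm3": None,
                              "new_lesion": False})
    meas = pd.DataFrame(mrows, columns=MEASUREMENT_COLUMNS)
    pats = pd.DataFrame(prows, columns=PATIENT_COLUMNS)
    return meas, pats


def frames_to_cohort(
    measurements: pd.DataFrame, patients: pd.DataFrame
) -> list[PatientTimeline]:
    """Rebuild timelines from the two interchange tables, validating on the way."""
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    missing |= set(PATIENT_COLUMNS) - set(patients.columns)
    if missing:
        raise DataValidationError(f"missing columns: {sorted(missing)}")
    timelines = []
    meas_by_pid = dict(tuple(measurements.groupby("patient_id", sort=False)))
    for prow in patients.to_dict("records"):
        pid = prow["patient_id"]
        sub = meas_by_pid.get(pid)
        if sub is None:
            raise DataValidationError(f"patient {pid}: no scans in measurement table")
        scans = []
        for scan_date, grp in sub.groupby("scan_date", sort=True):
            lesions = []
            for r in grp.to_dict("records"):
                if r["lesion_id"] in ("", None) or pd.isna(r["lesion_id"]):
                    continue
                lesions.append(LesionMeasurement(
                    lesion_id=str(r["lesion_id"]),
                    diam_longest=float(r["diam_longest_mm"]),
                    diam_perp=float(r["diam_perp_mm"]),
                    ce_volume=_opt_float(r["ce_volume_cm3"]),
                    is_new=bool(r["new_lesion"]),
                ))
            first = grp.iloc[0]
            scans.append(ScanRecord(
                scan_date=_parse_date(scan_date),
                lesions=tuple(lesions),
                t2flair_volume=_opt_float(first["t2flair_volume_cm3"]),
                t2flair_area=_opt_float(first["t2flair_area_mm2"]),
                t2flair_new_lesion=bool(first["t2flair_new_lesion"]),
                is_post_op=bool(first["is_post_op"]),
            ))
        scans.sort(key=lambda s: s.scan_date)
        timelines.append(PatientTimeline(
            patient_id=pid,
            arm=Arm(prow["arm"]),
            diagnosis_date=_parse_date(prow["diagnosis_date"]),
            scans=tuple(scans),
            immunotherapy_start=_parse_date(prow["immunotherapy_start"]),
            reresection_date=_parse_date(prow["reresection_date"]),
            last_contact_date=_parse_date(prow["last_contact_date"]),
            vital_status=VitalStatus(prow["vital_status"]),
        ))
    return timelines


def write_cohort_csv(timelines, measurements_path, patients_path) -> None:
    meas, pats = cohort_to_frames(timelines)
    meas.to_csv(measurements_path, index=False)
    pats.to_csv(patients_path, index=False)


def read_cohort_csv(measurements_path, patients_path) -> list[PatientTimeline]:
    meas = pd.read_csv(measurements_path, keep_default_na=True)
    pats = pd.read_csv(patients_path, keep_default_na=False)
    return frames_to_cohort(meas, pats)
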