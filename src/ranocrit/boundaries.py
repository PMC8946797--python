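"""Empirical recovery of the engines' decision thresholds.

Each function constructs minimal two-scan synthetic series, feeds them
through the public assessors, and locates the decision boundary by
bisection (continuous changes) or grid scan (measurability cutoffs,
timing windows). These probes treat the engines as black boxes, so they
double as end-to-end checks that every printed cutoff is recovered
exactly from behaviour rather than read off a constant.

All returned values are in the units the criteria are stated in:
percent change, cm / cm^3 for measurability, months for the
immunotherapy windows.
"""

from __future__ import annotations

import datetime as _dt
import math
from typing import Callable

from .cohort_model import (
    DAYS_PER_MONTH,
    Arm,
    Criterion,
    LesionMeasurement,
    PatientTimeline,
    ResponseLabel,
    ScanRecord,
    VitalStatus,
    aggregate_burden,
)
from .criteria_engine import (
    DEFAULT_THRESHOLDS,
    CriterionThresholds,
    assess,
    assess_irano,
)

__all__ = [
    "pd_2d_boundary_pct",
    "pd_vol_boundary_pct",
    "pr_vol_boundary_pct",
    "pr_2d_boundary_pct",
    "measurable_2d_cutoff_cm",
    "measurable_vol_cutoff_cm3",
    "t2_vol_boundary_pct",
    "irano_window_boundary_months",
    "irano_confirm_gap_months",
    "recover_all",
]

_D0 = _dt.date(2014, 1, 1)
_BISECT_ITERS = 60


def _two_scan_timeline(
    baseline_scan: ScanRecord, followup_scan: ScanRecord
) -> PatientTimeline:
    return PatientTimeline(
        patient_id="probe",
        arm=Arm.SOC,
        diagnosis_date=baseline_scan.scan_date - _dt.timedelta(days=3),
        scans=(baseline_scan, followup_scan),
        last_contact_date=followup_scan.scan_date,
        vital_status=VitalStatus.ALIVE_AT_CLOSURE,
    )


def _bisect(predicate: Callable[[float], bool], lo: float, hi: float) -> float:
    """Smallest x in [lo, hi] with predicate(x) true (step function)."""
    if predicate(lo):
        return lo
    if not predicate(hi):
        raise RuntimeError("predicate never fires on the bracket")
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return round(hi, 6)


def _lesion(diam_mm: float, volume: float | None = None,
            is_new: bool = False) -> LesionMeasurement:
    return LesionMeasurement("L1", diam_mm, diam_mm, volume, is_new)


def pd_2d_boundary_pct(th: CriterionThresholds = DEFAULT_THRESHOLDS) -> float:
    """Smallest % increase of the bidimensional product (vs nadir, no new
    lesion) called progressive disease by the MacDonald engine."""

    def is_pd(x: float) -> bool:
        d = 20.0 * math.sqrt(1.0 + x / 100.0)
        tl = _two_scan_timeline(
            ScanRecord(_D0, (_lesion(20.0),), 20.0, 1200.0, is_post_op=True),
            ScanRecord(_D0 + _dt.timedelta(days=60), (_lesion(d),), 20.0, 1200.0),
        )
        traj = assess(tl, Criterion.MACDONALD, th)
        return traj.per_scan_labels[0] is ResponseLabel.PD

    return _bisect(is_pd, 0.0, 100.0)


def pd_vol_boundary_pct(th: CriterionThresholds = DEFAULT_THRESHOLDS) -> float:
    """Smallest % increase of total CE volume called preliminary PD by the
    volumetric mRANO engine."""

    def is_pd(x: float) -> bool:
        v = 10.0 * (1.0 + x / 100.0)
        d = 10.0 * 2.0 * (3.0 * v / (4.0 * math.pi)) ** (1 / 3)
        tl = _two_scan_timeline(
            ScanRecord(_D0, (_lesion(25.0, 10.0),), 20.0, 1200.0, is_post_op=True),
            ScanRecord(_D0 + _dt.timedelta(days=60), (_lesion(d, v),), 20.0, 1200.0),
        )
        traj = assess(tl, Criterion.VOL_MRANO, th)
        return traj.per_scan_labels[0] is ResponseLabel.PRELIMINARY_PD

    return _bisect(is_pd, 0.0, 100.0)


def pr_vol_boundary_pct(th: CriterionThresholds = DEFAULT_THRESHOLDS) -> float:
    """Smallest % decrease of total CE volume (vs a measurable baseline)
    called preliminary partial response by the volumetric mRANO engine."""

    def is_pr(x: float) -> bool:
        v = 10.0 * (1.0 - x / 100.0)
        d = 10.0 * 2.0 * (3.0 * max(v, 1e-9) / (4.0 * math.pi)) ** (1 / 3)
        tl = _two_scan_timeline(
            ScanRecord(_D0, (_lesion(25.0, 10.0),), 20.0, 1200.0, is_post_op=True),
            ScanRecord(_D0 + _dt.timedelta(days=60), (_lesion(d, v),), 20.0, 1200.0),
        )
        traj = assess(tl, Criterion.VOL_MRANO, th)
        return traj.per_scan_labels[0] is ResponseLabel.PRELIMINARY_PR_OR_CR

    return _bisect(is_pr, 0.0, 99.0)


def pr_2d_boundary_pct(th: CriterionThresholds = DEFAULT_THRESHOLDS) -> float:
    """Smallest % decrease of the bidimensional product (stable T2) called
    partial response by the RANO engine."""

    def is_pr(x: float) -> bool:
        d = 20.0 * math.sqrt(max(1.0 - x / 100.0, 1e-12))
        tl = _two_scan_timeline(
            ScanRecord(_D0, (_lesion(20.0),), 20.0, 1200.0, is_post_op=True),
            ScanRecord(_D0 + _dt.timedelta(days=60), (_lesion(d),), 20.0, 1200.0),
        )
        traj = assess(tl, Criterion.RANO, th)
        return traj.per_scan_labels[0] is ResponseLabel.PR

    return _bisect(is_pr, 0.0, 99.0)


def measurable_2d_cutoff_cm(step_cm: float = 0.01) -> float:
    """Smallest equal-diameter lesion size (cm) flagged 2D-measurable."""
    lo, hi = 50, 150  # 0.50 .. 1.50 cm in 0.01 steps
    for i in range(lo, hi + 1):
        d_cm = i / 100.0
        burden = aggregate_burden(ScanRecord(_D0, (_lesion(d_cm * 10.0),)))
        if burden.measurable_2d:
            return d_cm
    raise RuntimeError("no measurable size found on the grid")


def measurable_vol_cutoff_cm3(step_cm3: float = 0.01) -> float:
    """Smallest total CE volume (cm^3) flagged volumetrically measurable."""
    for i in range(50, 151):
        v = i / 100.0
        burden = aggregate_burden(ScanRecord(_D0, (_lesion(8.0, v),)))
        if burden.measurable_vol:
            return v
    raise RuntimeError("no measurable volume found on the grid")


def t2_vol_boundary_pct(th: CriterionThresholds = DEFAULT_THRESHOLDS) -> float:
    """Smallest % increase of T2/FLAIR volume (stable CE, no new T2
    lesion) called progression by the Vol-RANO engine."""

    def is_pd(x: float) -> bool:
        tl = _two_scan_timeline(
            ScanRecord(_D0, (_lesion(15.0, 2.0),), 30.0, 1500.0, is_post_op=True),
            ScanRecord(_D0 + _dt.timedelta(days=60), (_lesion(15.0, 2.0),),
                       30.0 * (1.0 + x / 100.0), 1500.0),
        )
        traj = assess(tl, Criterion.VOL_RANO, th)
        return traj.per_scan_labels[0] is ResponseLabel.PD

    return _bisect(is_pd, 0.0, 200.0)


def _irano_timeline(onset_months: float, confirm_gap_months: float | None,
                    immuno_offset_months: float = 0.5):
    """Vaccine-arm timeline with a RANO-PD-sized enhancing change at
    ``onset_months`` after immunotherapy start, optionally followed by a
    persisting-PD confirmation scan ``confirm_gap_months`` later.
    Sub-day resolution via datetimes."""
    t0 = _dt.datetime(2014, 1, 1)
    immuno = t0 + _dt.timedelta(days=immuno_offset_months * DAYS_PER_MONTH)
    baseline = ScanRecord(t0, (_lesion(20.0, 4.0),), 30.0, 1500.0, is_post_op=True)
    onset_date = immuno + _dt.timedelta(days=onset_months * DAYS_PER_MONTH)
    scans = [baseline,
             ScanRecord(onset_date, (_lesion(26.0, 8.0),), 30.0, 1500.0)]
    if confirm_gap_months is not None:
        scans.append(ScanRecord(
            onset_date + _dt.timedelta(days=confirm_gap_months * DAYS_PER_MONTH),
            (_lesion(28.0, 9.0),), 30.0, 1500.0,
        ))
    last = scans[-1].scan_date
    tl = PatientTimeline(
        patient_id="probe",
        arm=Arm.SOC_PLUS_VACCINE,
        diagnosis_date=t0 - _dt.timedelta(days=3),
        scans=tuple(scans),
        immunotherapy_start=immuno,
        last_contact_date=last,
        vital_status=VitalStatus.ALIVE_AT_CLOSURE,
    )
    return tl


def irano_window_boundary_months(
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
    step_months: float = 0.1,
) -> float:
    """Longest onset time (months after immunotherapy start) at which a
    PD-sized change still triggers mandatory confirmation (preliminary
    PD) instead of immediate PD under the iRANO engine."""
    boundary = None
    t = step_months
    while t <= 9.0 + 1e-9:
        traj = assess_irano(_irano_timeline(round(t, 10), None), th)
        if traj.per_scan_labels[0] is ResponseLabel.PRELIMINARY_PD:
            boundary = t
        elif boundary is not None:
            break
        t = round(t + step_months, 10)
    if boundary is None:
        raise RuntimeError("no preliminary-PD onset found")
    return round(boundary, 6)


def irano_confirm_gap_months(
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
    step_months: float = 0.1,
) -> float:
    """Smallest interval between the preliminary-progression scan and a
    scan the iRANO engine accepts as confirming PD (preliminary PD fixed
    at month 2 after immunotherapy start, findings persisting)."""
    t = step_months
    while t <= 6.0 + 1e-9:
        traj = assess_irano(_irano_timeline(2.0, round(t, 10)), th)
        if traj.progression_event:
            return round(t, 6)
        t = round(t + step_months, 10)
    raise RuntimeError("no confirming gap found")


def recover_all(th: CriterionThresholds = DEFAULT_THRESHOLDS) -> dict[str, float]:
    """All nine empirical boundaries, keyed by a short descriptive name."""
    return {
        "pd_2d_increase_pct": pd_2d_boundary_pct(th),
        "pd_vol_increase_pct": pd_vol_boundary_pct(th),
        "pr_vol_decrease_pct": pr_vol_boundary_pct(th),
        "pr_2d_decrease_pct": pr_2d_boundary_pct(th),
        "measurable_2d_cutoff_cm": measurable_2d_cutoff_cm(),
        "measurable_vol_cutoff_cm3": measurable_vol_cutoff_cm3(),
        "t2_vol_increase_pct": t2_vol_boundary_pct(th),
        "irano_window_months": irano_window_boundary_months(th),
        "irano_confirm_gap_months": irano_confirm_gap_months(th),
    }
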