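"""PFS / OS / post-progression survival derivation.

Time origin for both PFS and OS is the pre-surgery MRI (date of
diagnosis). Censoring rules:

* OS — death is an event at the death date; loss to follow-up censors at
  the last visit; patients alive at study closure censor at the closure
  date.
* PFS — the first scan showing (confirmed, for confirmation-based
  criteria) progression is the event date; a re-resection without prior
  progression makes the last scan before re-resection the event date;
  otherwise the patient is censored at the last scan. An unresolved
  preliminary progression at the end of follow-up is not an event.
* PPS — defined only when PFS had an event; it is OS minus PFS with the
  OS event indicator.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Mapping, Optional

import pandas as pd

from .cohort_model import (
    Criterion,
    CriterionTrajectory,
    DataValidationError,
    EndpointRecord,
    PatientTimeline,
    VitalStatus,
    months_between,
)

__all__ = [
    "derive_os",
    "derive_pfs",
    "derive_pps",
    "derive_endpoints",
    "cohort_endpoints",
    "endpoints_frame",
]


def derive_os(
    tl: PatientTimeline, study_closure: Optional[_dt.date] = None
) -> tuple[float, bool]:
    """(os_months, os_event) from diagnosis to death / censoring."""
    if tl.vital_status is VitalStatus.DEAD:
        if tl.last_contact_date < tl.diagnosis_date:
            raise DataValidationError(
                f"patient {tl.patient_id}: death before diagnosis"
            )
        return months_between(tl.diagnosis_date, tl.last_contact_date), True
    if tl.vital_status is VitalStatus.LOST_TO_FOLLOW_UP:
        return months_between(tl.diagnosis_date, tl.last_contact_date), False
    # alive at closure
    if study_closure is None:
        study_closure = tl.last_contact_date
    return months_between(tl.diagnosis_date, study_closure), False


def derive_pfs(
    traj: CriterionTrajectory,
    tl: PatientTimeline,
    censored_last_scan_is_event: bool = False,
) -> tuple[float, bool]:
    """(pfs_months, pfs_event) for one criterion's trajectory.

    ``censored_last_scan_is_event`` reproduces the alternative literal
    reading in which a stable last scan is treated as the progression
    date rather than a censoring time; off by default.
    """
    last_scan_date = tl.scans[-1].scan_date
    prog_date = traj.progression_date if traj.progression_event else None
    if tl.reresection_date is not None:
        prior = [s.scan_date for s in tl.scans if s.scan_date < tl.reresection_date]
        if prior and (prog_date is None or prog_date > tl.reresection_date):
            # progression not diagnosed before re-resection: the last scan
            # prior to re-resection becomes the PD date
            return months_between(tl.diagnosis_date, max(prior)), True
    if prog_date is not None:
        if prog_date > tl.last_contact_date:
            raise DataValidationError(
                f"patient {tl.patient_id}: progression after last contact"
            )
        return months_between(tl.diagnosis_date, prog_date), True
    return (
        months_between(tl.diagnosis_date, last_scan_date),
        censored_last_scan_is_event,
    )


def derive_pps(
    pfs_months: float, pfs_event: bool, os_months: float, os_event: bool
) -> tuple[Optional[float], bool]:
    """(pps_months, pps_event): survival after progression.

    Undefined (None, False) without a progression event.
    """
    if not pfs_event:
        return None, False
    pps = os_months - pfs_months
    if pps < 0:
        raise DataValidationError("PPS negative: progression after death/censoring")
    return pps, os_event


def derive_endpoints(
    traj: CriterionTrajectory,
    tl: PatientTimeline,
    study_closure: Optional[_dt.date] = None,
) -> EndpointRecord:
    """Full endpoint record for one (patient, criterion)."""
    os_months, os_event = derive_os(tl, study_closure)
    pfs_months, pfs_event = derive_pfs(traj, tl)
    pfs_months = min(pfs_months, os_months)  # guard against sub-day rounding
    pps_months, pps_event = derive_pps(pfs_months, pfs_event, os_months, os_event)
    return EndpointRecord(
        patient_id=tl.patient_id,
        criterion=traj.criterion,
        pfs_months=pfs_months,
        pfs_event=pfs_event,
        os_months=os_months,
        os_event=os_event,
        pps_months=pps_months,
        pps_event=pps_event,
    )


def cohort_endpoints(
    trajectories: Mapping[str, Mapping[Criterion, CriterionTrajectory]],
    timelines: Iterable[PatientTimeline],
    study_closure: Optional[_dt.date] = None,
) -> list[EndpointRecord]:
    """Endpoint records for every (patient, criterion) pair available."""
    by_pid = {tl.patient_id: tl for tl in timelines}
    records = []
    for pid, per_crit in trajectories.items():
        tl = by_pid[pid]
        for traj in per_crit.values():
            records.append(derive_endpoints(traj, tl, study_closure))
    return records


def endpoints_frame(records: Iterable[EndpointRecord]) -> pd.DataFrame:
    """Tidy endpoint table, one row per (patient, criterion)."""
    return pd.DataFrame([
        {
            "patient_id": r.patient_id,
            "criterion": r.criterion.value,
            "pfs_months": r.pfs_months,
            "pfs_event": r.pfs_event,
            "os_months": r.os_months,
            "os_event": r.os_event,
            "pps_months": r.pps_months,
            "pps_event": r.pps_event,
        }
        for r in records
    ])
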