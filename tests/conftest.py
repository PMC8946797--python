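import datetime as dt

import pytest

from ranocrit import (
    Arm,
    LesionMeasurement,
    PatientTimeline,
    ScanRecord,
    VitalStatus,
)


def make_scan(date, lesions=(), t2v=None, t2a=None, post_op=False, t2new=False):
    return ScanRecord(
        scan_date=date,
        lesions=tuple(lesions),
        t2flair_volume=t2v,
        t2flair_area=t2a,
        t2flair_new_lesion=t2new,
        is_post_op=post_op,
    )


def make_timeline(scans, arm=Arm.SOC, immuno=None, reresection=None,
                  vital=VitalStatus.DEAD, last_contact=None,
                  diagnosis=None, patient_id="T01"):
    scans = tuple(scans)
    return PatientTimeline(
        patient_id=patient_id,
        arm=arm,
        diagnosis_date=diagnosis or scans[0].scan_date - dt.timedelta(days=3),
        scans=scans,
        immunotherapy_start=immuno,
        reresection_date=reresection,
        last_contact_date=last_contact or scans[-1].scan_date + dt.timedelta(days=90),
        vital_status=vital,
    )


@pytest.fixture
def fig1_like_timeline():
    """Vaccine-arm course with an early transient enhancing lesion
    (pseudoprogression) and late true progression.

    Designed label sequence: MacDonald/RANO/Vol-RANO call PD at the first
    follow-up (new lesion, doubled T2 volume, significant T2 area
    increase); mRANO/Vol-mRANO call preliminary PD there, adjudicate PsP
    at FU2 (no further growth), SD at FU3/FU4, and confirmed PD at FU5
    (threshold-crossing regrowth vs the post-PsP reference); iRANO calls
    preliminary PD at FU1 (within 6 months of immunotherapy) and
    confirmed PD at FU4 (significant T2 increase, >=3 months later).
    """
    les = LesionMeasurement
    scans = [
        make_scan(dt.date(2013, 1, 5), (), t2v=30.0, t2a=2000.0, post_op=True),
        make_scan(dt.date(2013, 3, 15),
                  (les("L1", 15.0, 12.0, 2.0, is_new=True),),
                  t2v=65.0, t2a=2700.0),
        make_scan(dt.date(2013, 6, 5),
                  (les("L1", 6.0, 5.0, 0.3),), t2v=36.0, t2a=2100.0),
        make_scan(dt.date(2013, 8, 27),
                  (les("L1", 5.0, 4.0, 0.2),), t2v=38.0, t2a=2150.0),
        make_scan(dt.date(2013, 11, 20),
                  (les("L1", 5.0, 4.0, 0.2),), t2v=55.0, t2a=2800.0),
        make_scan(dt.date(2014, 2, 20),
                  (les("L1", 18.0, 14.0, 2.5),), t2v=80.0, t2a=3400.0),
    ]
    return make_timeline(
        scans,
        arm=Arm.SOC_PLUS_VACCINE,
        immuno=dt.date(2013, 2, 23),
        diagnosis=dt.date(2013, 1, 2),
        vital=VitalStatus.DEAD,
        last_contact=dt.date(2014, 6, 1),
        patient_id="FIG1",
    )


@pytest.fixture
def fig2_like_timeline():
    """Course progressing purely as a non-enhancing T2/FLAIR abnormality.

    No enhancing lesion ever appears; T2 decreases at FU1 (best response,
    baseline reset) and then grows past both T2 thresholds from FU3 on.
    """
    scans = [
        make_scan(dt.date(2013, 1, 5), (), t2v=40.0, t2a=2400.0, post_op=True),
        make_scan(dt.date(2013, 3, 15), (), t2v=28.0, t2a=1900.0),
        make_scan(dt.date(2013, 6, 5), (), t2v=30.0, t2a=2000.0),
        make_scan(dt.date(2013, 8, 27), (), t2v=60.0, t2a=2500.0),
        make_scan(dt.date(2013, 11, 20), (), t2v=70.0, t2a=2700.0),
        make_scan(dt.date(2014, 2, 20), (), t2v=85.0, t2a=2900.0),
    ]
    return make_timeline(
        scans,
        arm=Arm.SOC_PLUS_VACCINE,
        immuno=dt.date(2013, 2, 23),
        diagnosis=dt.date(2013, 1, 2),
        vital=VitalStatus.DEAD,
        last_contact=dt.date(2014, 8, 1),
        patient_id="FIG2",
    )
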