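"""Assess one patient's MRI course under all six response criteria.

Builds a vaccine-arm course with an early transient enhancing lesion
(pseudoprogression) followed by true regrowth, and prints the per-scan
label each criterion assigns. The immediate-call criteria (MacDonald,
RANO, Vol-RANO) declare progression at the first follow-up; the
confirmation-based criteria (mRANO, Vol-mRANO) adjudicate
pseudoprogression there and only call progression at the late regrowth,
which is why their progression-free survival is longer.
"""

import datetime as dt

import ranocrit as rc

les = rc.LesionMeasurement
scans = [
    rc.ScanRecord(dt.date(2013, 1, 5), (), t2flair_volume=30.0,
                  t2flair_area=2000.0, is_post_op=True),
    rc.ScanRecord(dt.date(2013, 3, 15),
                  (les("L1", 15.0, 12.0, 2.0, is_new=True),),
                  t2flair_volume=65.0, t2flair_area=2700.0),
    rc.ScanRecord(dt.date(2013, 6, 5), (les("L1", 6.0, 5.0, 0.3),),
                  t2flair_volume=36.0, t2flair_area=2100.0),
    rc.ScanRecord(dt.date(2013, 8, 27), (les("L1", 5.0, 4.0, 0.2),),
                  t2flair_volume=38.0, t2flair_area=2150.0),
    rc.ScanRecord(dt.date(2013, 11, 20), (les("L1", 5.0, 4.0, 0.2),),
                  t2flair_volume=55.0, t2flair_area=2800.0),
    rc.ScanRecord(dt.date(2014, 2, 20), (les("L1", 18.0, 14.0, 2.5),),
                  t2flair_volume=80.0, t2flair_area=3400.0),
]
patient = rc.PatientTimeline(
    patient_id="EX01",
    arm=rc.Arm.SOC_PLUS_VACCINE,
    diagnosis_date=dt.date(2013, 1, 2),
    scans=tuple(scans),
    immunotherapy_start=dt.date(2013, 2, 23),
    last_contact_date=dt.date(2014, 6, 1),
    vital_status=rc.VitalStatus.DEAD,
)

print(f"{'criterion':<12}" + "".join(f"{'FU' + str(i + 1):<16}" for i in range(5)))
for crit, traj in rc.assess_all(patient).items():
    row = "".join(f"{lab.value:<16}" for lab in traj.per_scan_labels)
    event = (f"PD on {traj.progression_date}" if traj.progression_event
             else "no event")
    print(f"{crit.value:<12}{row} -> {event}")
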