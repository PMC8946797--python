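import datetime as dt

import pytest

import ranocrit as rc
from ranocrit.cohort_model import TumorBurden
from ranocrit.criteria_engine import (
    CriterionInapplicableError,
    T2Mode,
    T2Status,
    classify_2d,
    classify_t2,
    classify_vol,
    detect_t2_only,
)

from conftest import make_scan, make_timeline

L = rc.ResponseLabel
D0 = dt.date(2014, 1, 5)


def burden(sum2d=0.0, vol=0.0, t2v=None, t2a=None, new=False,
           new_meas=False, t2new=False):
    return TumorBurden(
        sum_product_2d=sum2d, total_ce_volume=vol, t2flair_volume=t2v,
        t2flair_area=t2a, measurable_2d=sum2d >= 100.0,
        measurable_vol=vol >= 1.0, any_new_lesion=new,
        any_new_measurable_lesion=new_meas,
        has_enhancing_disease=sum2d > 0 or vol > 0, t2flair_new_lesion=t2new,
    )


def _fu(day, lesions=(), t2v=30.0, t2a=2000.0):
    return make_scan(D0 + dt.timedelta(days=day), lesions, t2v=t2v, t2a=t2a)


def _lesion(lo, pe, vol=None, new=False):
    return rc.LesionMeasurement("L1", lo, pe, vol, new)


class TestSingleScanClassifiers:
    @pytest.mark.parametrize("cur,base,nad,expected", [
        (burden(126.0), burden(100.0), burden(100.0), L.PD),   # >= 25%
        (burden(100.0), burden(200.0), burden(200.0), L.PR),   # >= 50% drop
        (burden(100.0), burden(100.0), burden(100.0), L.SD),
        (burden(124.9), burden(100.0), burden(100.0), L.SD),
        (burden(50.0, new=True), burden(200.0), burden(200.0), L.PD),
        (burden(0.0), burden(200.0), burden(200.0), L.CR),
    ])
    def test_bidimensional_rules(self, cur, base, nad, expected):
        assert classify_2d(cur, base, nad) is expected

    def test_nonmeasurable_baseline_caps_response_at_sd(self):
        # large shrinkage relative to a sub-cutoff baseline is still SD
        assert classify_2d(burden(20.0), burden(80.0), burden(80.0)) is L.SD
        assert classify_2d(burden(0.0), burden(80.0), burden(80.0)) is L.SD

    @pytest.mark.parametrize("cur,base,nad,expected", [
        (burden(vol=14.1), burden(vol=10.0), burden(vol=10.0), L.PD),
        (burden(vol=3.4), burden(vol=10.0), burden(vol=10.0), L.PR),
        (burden(vol=13.9), burden(vol=10.0), burden(vol=10.0), L.SD),
    ])
    def test_volumetric_rules(self, cur, base, nad, expected):
        assert classify_vol(cur, base, nad) is expected

    def test_narrow_band_where_2d_and_volumetric_calls_disagree(self):
        # linear factor 1.1185: product grows 25.1% but volume only 39.9%
        s = 1.1185
        cur = burden(sum2d=400 * s * s, vol=4.18879 * s**3)
        base = burden(sum2d=400.0, vol=4.18879)
        assert classify_2d(cur, base, base) is L.PD
        assert classify_vol(cur, base, base) is L.SD

    @pytest.mark.parametrize("cur,ref,mode,expected", [
        (burden(t2v=61.0), burden(t2v=30.0), T2Mode.VOLUMETRIC,
         T2Status.PROGRESSED),
        (burden(t2v=30.0), burden(t2v=30.0), T2Mode.VOLUMETRIC,
         T2Status.STABLE),
        (burden(t2v=79.0), burden(t2v=40.0), T2Mode.VOLUMETRIC,
         T2Status.STABLE),  # 97.5% < 100%
        (burden(t2v=14.0), burden(t2v=30.0), T2Mode.VOLUMETRIC,
         T2Status.IMPROVED),
        (burden(t2a=2500.0), burden(t2a=2000.0), T2Mode.AREA_2D,
         T2Status.PROGRESSED),
        (burden(t2a=2499.0), burden(t2a=2000.0), T2Mode.AREA_2D,
         T2Status.STABLE),
        (burden(t2v=30.0, t2new=True), burden(t2v=30.0), T2Mode.VOLUMETRIC,
         T2Status.PROGRESSED),
    ])
    def test_t2_flair_rules(self, cur, ref, mode, expected):
        assert classify_t2(cur, ref, mode) is expected

    def test_missing_t2_degrades_to_stable(self):
        assert classify_t2(burden(), burden(t2v=30.0),
                           T2Mode.VOLUMETRIC) is T2Status.STABLE


class TestMacdonald:
    def test_transient_bump_is_called_pd_without_confirmation(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], post_op=True),
            _fu(90, [_lesion(23, 23)]),    # +32% product
            _fu(180, [_lesion(20, 20)]),
        ])
        traj = rc.assess_macdonald(tl)
        assert traj.per_scan_labels[0] is L.PD
        assert traj.progression_event
        assert traj.progression_date == tl.scans[1].scan_date

    def test_monotone_shrinkage_never_progresses(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], post_op=True),
            _fu(90, [_lesion(18, 18)]),
            _fu(180, [_lesion(15, 15)]),
        ])
        traj = rc.assess_macdonald(tl)
        assert not traj.progression_event
        assert L.PD not in traj.per_scan_labels

    def test_no_post_op_scan_is_a_configuration_error(self):
        tl = make_timeline([make_scan(D0), _fu(90)])
        with pytest.raises(rc.DataValidationError):
            rc.assess_macdonald(tl)


class TestRano:
    def test_t2_progression_dominates_ce_shrinkage(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], t2v=30, t2a=2000, post_op=True),
            _fu(90, [_lesion(13, 13)], t2v=70, t2a=2700),  # PR-sized CE drop
        ])
        traj = rc.assess_rano(tl)
        assert traj.per_scan_labels[0] is L.PD

    def test_all_stable_course_stays_sd(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(15, 15)], post_op=True),
            _fu(90, [_lesion(15, 15)]),
            _fu(180, [_lesion(16, 15)]),
        ])
        traj = rc.assess_rano(tl)
        assert traj.per_scan_labels == [L.SD, L.SD]

    def test_partial_response_requires_stable_t2(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], t2v=30, t2a=2000, post_op=True),
            _fu(90, [_lesion(13, 13)], t2v=30, t2a=2000),
        ])
        assert rc.assess_rano(tl).per_scan_labels[0] is L.PR


class TestVolRano:
    def test_sub_threshold_volume_growth_with_stable_t2_is_sd(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20, 10.0)], t2v=30, t2a=2000,
                      post_op=True),
            _fu(90, [_lesion(22, 22, 13.9)], t2v=30, t2a=2000),  # +39%
        ])
        assert rc.assess_vol_rano(tl).per_scan_labels[0] is L.SD

    def test_new_measurable_lesion_progresses_regardless_of_volumes(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20, 10.0)], t2v=30, t2a=2000,
                      post_op=True),
            make_scan(D0 + dt.timedelta(days=90),
                      [_lesion(20, 20, 10.0),
                       rc.LesionMeasurement("L2", 12, 11, 1.2, is_new=True)],
                      t2v=30, t2a=2000),
        ])
        assert rc.assess_vol_rano(tl).per_scan_labels[0] is L.PD

    def test_missing_volumes_make_criterion_inapplicable(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], t2v=30, t2a=2000, post_op=True),
            _fu(90, [_lesion(22, 22)], t2v=30, t2a=2000),
        ])
        with pytest.raises(CriterionInapplicableError):
            rc.assess_vol_rano(tl)


class TestMrano:
    def test_monotone_growth_confirms_pd_with_backdated_date(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], post_op=True),
            _fu(90, [_lesion(23, 23)]),     # +32% -> preliminary
            _fu(180, [_lesion(27, 27)]),    # +38% vs preliminary -> confirmed
        ])
        traj = rc.assess_mrano(tl)
        assert traj.per_scan_labels == [L.PRELIMINARY_PD, L.PD]
        assert traj.progression_event
        assert traj.progression_date == tl.scans[1].scan_date  # backdated
        assert not traj.psp_confirmed

    def test_confirming_scan_date_used_when_backdating_disabled(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], post_op=True),
            _fu(90, [_lesion(23, 23)]),
            _fu(180, [_lesion(27, 27)]),
        ])
        th = rc.CriterionThresholds(backdate_progression=False)
        traj = rc.assess_mrano(tl, th)
        assert traj.progression_date == tl.scans[2].scan_date

    def test_quiet_course_never_preliminary(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], post_op=True),
            _fu(90, [_lesion(20, 20)]),
            _fu(180, [_lesion(21, 21)]),
        ])
        traj = rc.assess_mrano(tl)
        assert traj.per_scan_labels == [L.SD, L.SD]
        assert not traj.psp_confirmed

    def test_unresolved_preliminary_at_end_is_not_an_event(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], post_op=True),
            _fu(90, [_lesion(23, 23)]),
        ])
        traj = rc.assess_mrano(tl)
        assert traj.per_scan_labels == [L.PRELIMINARY_PD]
        assert not traj.progression_event

    def test_regression_after_preliminary_adjudicates_psp(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(20, 20)], post_op=True),
            _fu(90, [_lesion(23, 23)]),
            _fu(180, [_lesion(20, 20)]),
        ])
        traj = rc.assess_mrano(tl)
        assert traj.per_scan_labels == [L.PRELIMINARY_PD, L.PSP_ADJUDICATED]
        assert traj.psp_confirmed and not traj.progression_event


class TestIrano:
    def _tl(self, onset_day, extra=None):
        scans = [make_scan(D0, [_lesion(15, 15, 2.0)], t2v=30, t2a=2000,
                           post_op=True),
                 make_scan(D0 + dt.timedelta(days=onset_day),
                           [_lesion(20, 20, 4.5)], t2v=30, t2a=2000)]
        if extra is not None:
            scans.append(extra)
        return make_timeline(scans, arm=rc.Arm.SOC_PLUS_VACCINE,
                             immuno=D0 + dt.timedelta(days=14))

    def test_progression_after_window_is_immediate(self):
        traj = rc.assess_irano(self._tl(onset_day=14 + 244))  # ~8 months
        assert traj.per_scan_labels[0] is L.PD
        assert traj.progression_event

    def test_progression_within_window_needs_confirmation(self):
        traj = rc.assess_irano(self._tl(onset_day=75))
        assert traj.per_scan_labels[0] is L.PRELIMINARY_PD
        assert not traj.progression_event

    def test_regression_at_eligible_scan_adjudicates_psp(self):
        extra = make_scan(D0 + dt.timedelta(days=75 + 100),
                          [_lesion(15, 15, 2.0)], t2v=30, t2a=2000)
        traj = rc.assess_irano(self._tl(onset_day=75, extra=extra))
        assert traj.per_scan_labels == [L.PRELIMINARY_PD, L.PSP_ADJUDICATED]
        assert traj.psp_confirmed and not traj.progression_event

    def test_persistent_findings_confirm_with_backdating(self):
        extra = make_scan(D0 + dt.timedelta(days=75 + 100),
                          [_lesion(21, 20, 5.0)], t2v=30, t2a=2000)
        traj = rc.assess_irano(self._tl(onset_day=75, extra=extra))
        assert traj.per_scan_labels == [L.PRELIMINARY_PD, L.PD]
        assert traj.progression_event
        assert traj.progression_date == D0 + dt.timedelta(days=75)

    def test_requires_immunotherapy_start(self):
        tl = make_timeline([
            make_scan(D0, [_lesion(15, 15, 2.0)], t2v=30, t2a=2000,
                      post_op=True),
            _fu(90, [_lesion(20, 20, 4.5)]),
        ])
        with pytest.raises(CriterionInapplicableError):
            rc.assess_irano(tl)

    def test_reduces_to_rano_when_all_findings_after_window(self):
        scans = [make_scan(D0, [_lesion(15, 15, 2.0)], t2v=30, t2a=2000,
                           post_op=True)]
        for i, d in enumerate((200, 290, 380)):
            grow = 15 + 3 * (i + 1)
            scans.append(make_scan(D0 + dt.timedelta(days=d),
                                   [_lesion(grow, grow, 2.0 + i)],
                                   t2v=30, t2a=2000))
        tl = make_timeline(scans, arm=rc.Arm.SOC_PLUS_VACCINE, immuno=D0)
        ir = rc.assess_irano(tl)
        ra = rc.assess_rano(tl)
        assert ir.per_scan_labels == ra.per_scan_labels
        assert ir.progression_date == ra.progression_date


class TestTrajectoryProperties:
    def test_labels_invariant_under_date_translation(self):
        cohort = rc.simulate_cohort(rc.SimulationConfig(n_patients=20, seed=9))
        shift = dt.timedelta(days=137)
        for tl in cohort.timelines:
            shifted = rc.PatientTimeline(
                patient_id=tl.patient_id, arm=tl.arm,
                diagnosis_date=tl.diagnosis_date + shift,
                scans=tuple(
                    rc.ScanRecord(s.scan_date + shift, s.lesions,
                                  s.t2flair_volume, s.t2flair_area,
                                  s.t2flair_new_lesion, s.is_post_op)
                    for s in tl.scans),
                immunotherapy_start=(tl.immunotherapy_start + shift
                                     if tl.immunotherapy_start else None),
                last_contact_date=tl.last_contact_date + shift,
                vital_status=tl.vital_status,
            )
            for crit, traj in rc.assess_all(tl).items():
                traj2 = rc.assess(shifted, crit)
                assert traj.per_scan_labels == traj2.per_scan_labels

    def test_nonmeasurable_baseline_cohort_never_responds(self):
        # gross total resection: best attainable response is SD
        cohort = rc.simulate_cohort(rc.SimulationConfig(n_patients=60, seed=5))
        banned = {L.PR, L.CR, L.PRELIMINARY_PR_OR_CR,
                  L.PSEUDORESPONSE_ADJUDICATED}
        for tl in cohort.timelines:
            for traj in rc.assess_all(tl).values():
                assert not banned & set(traj.per_scan_labels)


class TestDetectT2Only:
    def test_lead_time_between_t2_and_ce_progression(self):
        scans = [make_scan(D0, (), t2v=30, t2a=2000, post_op=True)]
        # T2 doubles at month 5; enhancing lesion appears at month 15
        for m, (t2v, les) in {
            5: (61.0, ()), 8: (70.0, ()), 11: (80.0, ()),
            15: (95.0, (_lesion(14, 12, 1.5, new=True),)),
        }.items():
            scans.append(make_scan(D0 + dt.timedelta(days=round(m * 30.4375)),
                                   les, t2v=t2v, t2a=2000.0))
        tl = make_timeline(scans)
        traj = rc.assess_vol_rano(tl)
        assert traj.t2_only_progression
        assert traj.t2_lead_months == pytest.approx(10.0, abs=0.05)

    def test_simultaneous_firing_is_not_t2_only(self):
        tl = make_timeline([
            make_scan(D0, (), t2v=30, t2a=2000, post_op=True),
            make_scan(D0 + dt.timedelta(days=150),
                      (_lesion(14, 12, 1.5, new=True),), t2v=61, t2a=2100),
        ])
        traj = rc.assess_vol_rano(tl)
        assert traj.progression_event and not traj.t2_only_progression
        assert detect_t2_only(traj, tl) == (False, None)
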