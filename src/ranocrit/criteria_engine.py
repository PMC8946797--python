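"""Longitudinal response-classification engines.

Implements the six criteria as per-scan state machines over aggregated
tumor burdens:

* **MacDonald** — enhancing disease only, bidimensional product, no
  confirmation (>=25% increase vs nadir or a new lesion -> PD).
* **RANO** — MacDonald's enhancing rules plus a T2/FLAIR compartment
  (significant 2D increase -> PD); CR/PR require stable/improved T2.
* **Vol-RANO** — RANO with volumetric enhancing rules (>=40% increase /
  >=65% decrease) and volumetric T2 (>=100% increase -> PD).
* **mRANO / Vol-mRANO** — enhancing-only rules with a confirmation scan:
  the first threshold crossing is preliminary PD; the next scan either
  confirms (further crossing vs the preliminary scan) or adjudicates
  pseudoprogression, after which the reference baseline resets to the
  adjudication scan.
* **iRANO** — RANO rules, but progression findings within 6 months of
  immunotherapy start only count once a scan >= 3 months later still
  meets the progression definition against the reference in force at the
  preliminary call.

Reference handling shared by all engines: the baseline is the post-op
scan, and it resets to any later scan showing strictly smaller disease
(best response); the nadir is the running minimum burden since the
current baseline. All thresholds are ``>=`` — a tie counts as crossing.
"""

from __future__ import annotations

import datetime as _dt
import enum
import logging
from dataclasses import dataclass
from typing import Optional

from .cohort_model import (
    DEFAULT_CUTOFFS,
    Criterion,
    CriterionTrajectory,
    DataValidationError,
    MeasurabilityCutoffs,
    PatientTimeline,
    ResponseLabel,
    TumorBurden,
    aggregate_burden,
    months_between,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CriterionThresholds",
    "T2Mode",
    "T2Status",
    "CriterionInapplicableError",
    "classify_2d",
    "classify_vol",
    "classify_t2",
    "assess_macdonald",
    "assess_rano",
    "assess_vol_rano",
    "assess_mrano",
    "assess_irano",
    "assess",
    "assess_all",
    "detect_t2_only",
]


class CriterionInapplicableError(ValueError):
    """The criterion cannot be evaluated for this patient (e.g. iRANO
    without an immunotherapy start date, or volumetric criteria without
    segmented volumes)."""


class T2Mode(str, enum.Enum):
    AREA_2D = "area_2d"
    VOLUMETRIC = "volumetric"


class T2Status(str, enum.Enum):
    IMPROVED = "improved"
    STABLE = "stable"
    PROGRESSED = "progressed"


@dataclass(frozen=True)
class CriterionThresholds:
    """Decision thresholds of the criteria family.

    Fractions are relative changes: PD fires at ``>= (1+f) x reference``,
    PR at ``<= (1-g) x baseline``. The 2D T2/FLAIR "significant increase"
    of RANO/iRANO is reader judgment in the source criteria; it is
    operationalized here as a fractional area increase (default 25%,
    mirroring the enhancing 2D threshold) or a new T2 lesion.
    """

    pd_2d_increase: float = 0.25
    pr_2d_decrease: float = 0.50
    pd_vol_increase: float = 0.40
    pr_vol_decrease: float = 0.65
    t2_vol_pd_increase: float = 1.00
    t2_2d_significant_increase: float = 0.25
    irano_window_months: float = 6.0
    irano_confirm_min_gap_months: float = 3.0
    mrano_confirm_window_weeks: tuple[float, float] = (4.0, 8.0)
    mrano_strict_window: bool = False
    backdate_progression: bool = True
    target_lesion_cap: Optional[int] = None

    def __post_init__(self) -> None:
        fracs = (self.pd_2d_increase, self.pr_2d_decrease, self.pd_vol_increase,
                 self.pr_vol_decrease, self.t2_vol_pd_increase,
                 self.t2_2d_significant_increase)
        if any(f <= 0 for f in fracs):
            raise DataValidationError("threshold fractions must be positive")
        if self.irano_confirm_min_gap_months <= 0:
            raise DataValidationError("iRANO confirmation gap must be positive")


DEFAULT_THRESHOLDS = CriterionThresholds()


# ---------------------------------------------------------------------------
# Single-scan classifiers


def classify_2d(
    current: TumorBurden,
    baseline: TumorBurden,
    nadir: TumorBurden,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
) -> ResponseLabel:
    """Bidimensional enhancing-disease call. Precedence PD > CR > PR > SD.

    PD: new lesion, or measurable disease with cross-section product
    >= (1 + pd_2d_increase) x nadir. PR/CR require a measurable baseline;
    with a nonmeasurable baseline the best attainable response is SD.
    """
    if current.any_new_lesion:
        return ResponseLabel.PD
    if current.measurable_2d and current.sum_product_2d >= (
        1.0 + th.pd_2d_increase
    ) * nadir.sum_product_2d:
        return ResponseLabel.PD
    if baseline.measurable_2d:
        if not current.has_enhancing_disease:
            return ResponseLabel.CR
        if current.sum_product_2d <= (1.0 - th.pr_2d_decrease) * baseline.sum_product_2d:
            return ResponseLabel.PR
    return ResponseLabel.SD


def classify_vol(
    current: TumorBurden,
    baseline: TumorBurden,
    nadir: TumorBurden,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
) -> ResponseLabel:
    """Volumetric enhancing-disease call (total CE volume; 40%/65% rules)."""
    if current.any_new_lesion:
        return ResponseLabel.PD
    if current.measurable_vol and current.total_ce_volume >= (
        1.0 + th.pd_vol_increase
    ) * nadir.total_ce_volume:
        return ResponseLabel.PD
    if baseline.measurable_vol:
        if not current.has_enhancing_disease:
            return ResponseLabel.CR
        if current.total_ce_volume <= (
            1.0 - th.pr_vol_decrease
        ) * baseline.total_ce_volume:
            return ResponseLabel.PR
    return ResponseLabel.SD


def classify_t2(
    current: TumorBurden,
    reference: TumorBurden,
    mode: T2Mode = T2Mode.AREA_2D,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
) -> T2Status:
    """T2/FLAIR compartment call vs the baseline/best-response reference.

    Volumetric mode fires at >=100% volume increase, 2D mode at the
    operationalized significant area increase; a new T2 lesion always
    fires. Improvement is the ratio-symmetric decrease (below
    reference/(1+f)). Missing T2 measurements degrade to "stable" with a
    logged warning.
    """
    if current.t2flair_new_lesion:
        return T2Status.PROGRESSED
    if mode is T2Mode.VOLUMETRIC:
        cur, ref = current.t2flair_volume, reference.t2flair_volume
        f = th.t2_vol_pd_increase
    else:
        cur, ref = current.t2flair_area, reference.t2flair_area
        f = th.t2_2d_significant_increase
    if cur is None or ref is None:
        logger.warning("missing T2/FLAIR measurement; treating as stable")
        return T2Status.STABLE
    if ref <= 0:
        return T2Status.PROGRESSED if cur > 0 else T2Status.STABLE
    if cur >= (1.0 + f) * ref:
        return T2Status.PROGRESSED
    if cur <= ref / (1.0 + f):
        return T2Status.IMPROVED
    return T2Status.STABLE


# ---------------------------------------------------------------------------
# Longitudinal engine


@dataclass
class _Pending:
    """A preliminary call awaiting confirmation."""

    kind: ResponseLabel            # PRELIMINARY_PD or PRELIMINARY_PR_OR_CR
    scan_index: int                # follow-up index of the preliminary scan
    burden: TumorBurden            # burden at the preliminary scan
    date: _dt.date
    baseline_idx: int              # reference frozen at the preliminary call
    nadir_idx: int


@dataclass(frozen=True)
class _EngineSpec:
    criterion: Criterion
    volumetric: bool
    t2_mode: Optional[T2Mode]
    confirmation: Optional[str]    # None | "mrano" | "irano"


_SPECS = {
    Criterion.MACDONALD: _EngineSpec(Criterion.MACDONALD, False, None, None),
    Criterion.RANO: _EngineSpec(Criterion.RANO, False, T2Mode.AREA_2D, None),
    Criterion.VOL_RANO: _EngineSpec(Criterion.VOL_RANO, True, T2Mode.VOLUMETRIC, None),
    Criterion.MRANO: _EngineSpec(Criterion.MRANO, False, None, "mrano"),
    Criterion.VOL_MRANO: _EngineSpec(Criterion.VOL_MRANO, True, None, "mrano"),
    Criterion.IRANO: _EngineSpec(Criterion.IRANO, False, T2Mode.AREA_2D, "irano"),
}


def _metric(b: TumorBurden, volumetric: bool) -> float:
    return b.total_ce_volume if volumetric else b.sum_product_2d


def _t2_value(b: TumorBurden, mode: T2Mode) -> Optional[float]:
    return b.t2flair_volume if mode is T2Mode.VOLUMETRIC else b.t2flair_area


def _classify_ce(cur, base, nad, th, volumetric):
    return (classify_vol if volumetric else classify_2d)(cur, base, nad, th)


def _growth_confirmed(cur: TumorBurden, ref: TumorBurden, th, volumetric) -> bool:
    """Further threshold-crossing increase of ``cur`` vs a reference scan."""
    if volumetric:
        return cur.measurable_vol and cur.total_ce_volume >= (
            1.0 + th.pd_vol_increase
        ) * ref.total_ce_volume
    return cur.measurable_2d and cur.sum_product_2d >= (
        1.0 + th.pd_2d_increase
    ) * ref.sum_product_2d


class _Engine:
    """Shared longitudinal state machine; criterion quirks via _EngineSpec."""

    def __init__(
        self,
        tl: PatientTimeline,
        th: CriterionThresholds,
        spec: _EngineSpec,
        cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS,
        immunotherapy_start: Optional[_dt.date] = None,
    ) -> None:
        self.tl = tl
        self.th = th
        self.spec = spec
        self.cutoffs = cutoffs
        self.immunotherapy_start = immunotherapy_start
        post_op = tl.post_op_index
        if post_op + 1 >= len(tl.scans):
            raise DataValidationError(
                f"patient {tl.patient_id}: no follow-up scan after baseline"
            )
        scans = tl.scans[post_op:]
        if spec.volumetric:
            for s in scans:
                if any(les.ce_volume is None for les in s.lesions):
                    raise CriterionInapplicableError(
                        f"patient {tl.patient_id}: lesion volumes missing, "
                        f"{spec.criterion.value} inapplicable"
                    )
        self.scans = scans                       # index 0 = post-op baseline
        self.burdens = [aggregate_burden(s, cutoffs) for s in scans]

    # -- reference tracking -------------------------------------------------

    def _smaller(self, i: int, j: int) -> bool:
        """Is the disease on scan i strictly smaller than on scan j?

        Ordered on the enhancing metric; for criteria with a T2 component
        equal enhancing burden is broken by the T2 measure, so a pure-T2
        best response (Fig-2-type course) also resets the baseline.
        """
        a, b = self.burdens[i], self.burdens[j]
        ma, mb = _metric(a, self.spec.volumetric), _metric(b, self.spec.volumetric)
        if ma < mb:
            return True
        if ma == mb and self.spec.t2_mode is not None:
            ta = _t2_value(a, self.spec.t2_mode)
            tb = _t2_value(b, self.spec.t2_mode)
            if ta is not None and tb is not None and ta < tb:
                return True
        return False

    def _nadir_index(self, baseline_idx: int, upto: int) -> int:
        """Scan with minimal enhancing metric in [baseline_idx, upto]."""
        best = baseline_idx
        for i in range(baseline_idx, upto + 1):
            if _metric(self.burdens[i], self.spec.volumetric) < _metric(
                self.burdens[best], self.spec.volumetric
            ):
                best = i
        return best

    # -- per-scan RANO-style call -------------------------------------------

    def _call(self, k: int, baseline_idx: int, nadir_idx: int):
        """(label, ce_fired, t2_fired) for follow-up scan k vs references."""
        cur = self.burdens[k]
        base = self.burdens[baseline_idx]
        nad = self.burdens[nadir_idx]
        label = _classify_ce(cur, base, nad, self.th, self.spec.volumetric)
        ce_fired = label is ResponseLabel.PD
        t2_fired = False
        if self.spec.t2_mode is not None:
            t2s = classify_t2(cur, base, self.spec.t2_mode, self.th)
            if t2s is T2Status.PROGRESSED:
                t2_fired = True
                label = ResponseLabel.PD
            elif label in (ResponseLabel.CR, ResponseLabel.PR) and t2s not in (
                T2Status.STABLE, T2Status.IMPROVED,
            ):
                label = ResponseLabel.SD
        return label, ce_fired, t2_fired

    # -- main loop ----------------------------------------------------------

    def run(self) -> CriterionTrajectory:
        th, spec = self.th, self.spec
        traj = CriterionTrajectory(
            criterion=spec.criterion,
            patient_id=self.tl.patient_id,
            per_scan_labels=[],
            scan_dates=[s.scan_date for s in self.scans[1:]],
        )
        baseline_idx = 0
        pending: Optional[_Pending] = None
        post_psp = False
        confirmed = False
        confirmed_date: Optional[_dt.date] = None

        for k in range(1, len(self.scans)):
            nadir_idx = self._nadir_index(baseline_idx, k - 1)
            cur = self.burdens[k]
            label: Optional[ResponseLabel] = None
            raw_label, ce_fired, t2_fired = self._call(k, baseline_idx, nadir_idx)

            if confirmed:
                # absorbing PD state: keep reporting PD; raw flags above are
                # still recorded (vs the references frozen at the event) so
                # T2-only lead times can span the post-event course.
                label = ResponseLabel.PD
            elif pending is not None and pending.kind is ResponseLabel.PRELIMINARY_PD:
                if spec.confirmation == "mrano":
                    if _growth_confirmed(cur, pending.burden, th, spec.volumetric) or (
                        cur.any_new_measurable_lesion
                    ):
                        confirmed = True
                        confirmed_date = (
                            pending.date if th.backdate_progression
                            else self.scans[k].scan_date
                        )
                        label = ResponseLabel.PD
                    else:
                        # regression or stability vs the preliminary scan:
                        # pseudoprogression; the adjudication scan becomes
                        # the new reference baseline.
                        traj.psp_confirmed = True
                        label = ResponseLabel.PSP_ADJUDICATED
                        baseline_idx = k
                        post_psp = True
                    if (
                        th.mrano_strict_window
                        and not self._within_mrano_window(pending.scan_index, k)
                    ):
                        logger.warning(
                            "patient %s: mRANO confirmation outside the %s-week "
                            "window", self.tl.patient_id, th.mrano_confirm_window_weeks,
                        )
                    pending = None
                else:  # irano
                    pd_met, p_ce, p_t2 = self._irano_pd_met(k, pending)
                    ce_fired, t2_fired = ce_fired or p_ce, t2_fired or p_t2
                    gap = months_between(pending.date, self.scans[k].scan_date)
                    if gap >= th.irano_confirm_min_gap_months:
                        if pd_met:
                            confirmed = True
                            confirmed_date = (
                                pending.date if th.backdate_progression
                                else self.scans[k].scan_date
                            )
                            label = ResponseLabel.PD
                        else:
                            traj.psp_confirmed = True
                            label = ResponseLabel.PSP_ADJUDICATED
                            baseline_idx = k
                        pending = None
                    else:
                        # too early to decide; report the preliminary state
                        # while findings persist, otherwise the plain call.
                        label = (
                            ResponseLabel.PRELIMINARY_PD
                            if pd_met or raw_label is ResponseLabel.PD
                            else raw_label
                        )
            elif pending is not None:
                # preliminary PR/CR (confirmation criteria only)
                if raw_label is ResponseLabel.PD:
                    label = ResponseLabel.PSEUDORESPONSE_ADJUDICATED
                    pending = _Pending(
                        ResponseLabel.PRELIMINARY_PD, k, cur,
                        self.scans[k].scan_date, baseline_idx, nadir_idx,
                    )
                else:
                    label = raw_label  # durable PR/CR (or SD)
                    pending = None

            if label is None:
                # no pending state: interpret the plain per-scan call
                if raw_label is ResponseLabel.PD:
                    if spec.confirmation is None:
                        confirmed = True
                        confirmed_date = self.scans[k].scan_date
                        label = ResponseLabel.PD
                    elif spec.confirmation == "mrano":
                        if post_psp:
                            # re-progression beyond the PsP-adjudicated level
                            # counts as confirmed outright
                            confirmed = True
                            confirmed_date = self.scans[k].scan_date
                            label = ResponseLabel.PD
                        else:
                            label = ResponseLabel.PRELIMINARY_PD
                            pending = _Pending(
                                ResponseLabel.PRELIMINARY_PD, k, cur,
                                self.scans[k].scan_date, baseline_idx, nadir_idx,
                            )
                    else:  # irano
                        # signed: findings before immunotherapy start are
                        # not immune-related and progress immediately
                        delta = self.scans[k].scan_date - self.immunotherapy_start
                        months_since_immuno = (
                            delta.total_seconds() / 86400.0 / 30.4375
                        )
                        if 0.0 <= months_since_immuno <= th.irano_window_months:
                            label = ResponseLabel.PRELIMINARY_PD
                            pending = _Pending(
                                ResponseLabel.PRELIMINARY_PD, k, cur,
                                self.scans[k].scan_date, baseline_idx, nadir_idx,
                            )
                        else:
                            confirmed = True
                            confirmed_date = self.scans[k].scan_date
                            label = ResponseLabel.PD
                elif raw_label in (ResponseLabel.PR, ResponseLabel.CR) and (
                    spec.confirmation == "mrano"
                ):
                    label = ResponseLabel.PRELIMINARY_PR_OR_CR
                    pending = _Pending(
                        ResponseLabel.PRELIMINARY_PR_OR_CR, k, cur,
                        self.scans[k].scan_date, baseline_idx, nadir_idx,
                    )
                else:
                    label = raw_label

            traj.per_scan_labels.append(label)
            traj.ce_progression_flags.append(ce_fired)
            traj.t2_progression_flags.append(t2_fired)
            traj.reference_log.append({
                "scan_index": k,
                "baseline_index": baseline_idx,
                "nadir_index": nadir_idx,
                "state": label.value,
                "pending": pending.kind.value if pending else None,
            })

            # best-response baseline reset (only while no event and no
            # pending adjudication, and never backwards past a PsP reset)
            if not confirmed and pending is None and self._smaller(k, baseline_idx):
                baseline_idx = k

        traj.progression_event = confirmed
        traj.progression_date = confirmed_date
        self._finalize_t2_only(traj)
        return traj

    # -- helpers ------------------------------------------------------------

    def _within_mrano_window(self, prelim_idx: int, confirm_idx: int) -> bool:
        gap_days = (
            self.scans[confirm_idx].scan_date - self.scans[prelim_idx].scan_date
        ).total_seconds() / 86400.0 if isinstance(
            self.scans[confirm_idx].scan_date, _dt.datetime
        ) else (
            self.scans[confirm_idx].scan_date - self.scans[prelim_idx].scan_date
        ).days
        lo, hi = self.th.mrano_confirm_window_weeks
        return lo * 7.0 <= gap_days <= hi * 7.0

    def _irano_pd_met(self, k: int, pending: _Pending):
        """RANO-PD findings on scan k vs the reference frozen at the
        preliminary call. Returns (met, ce_fired, t2_fired)."""
        cur = self.burdens[k]
        base = self.burdens[pending.baseline_idx]
        nad_idx = self._nadir_index(pending.baseline_idx, pending.scan_index - 1)
        nad = self.burdens[nad_idx]
        ce = _classify_ce(cur, base, nad, self.th, self.spec.volumetric)
        ce_fired = ce is ResponseLabel.PD
        t2_fired = (
            self.spec.t2_mode is not None
            and classify_t2(cur, base, self.spec.t2_mode, self.th)
            is T2Status.PROGRESSED
        )
        return ce_fired or t2_fired, ce_fired, t2_fired

    def _finalize_t2_only(self, traj: CriterionTrajectory) -> None:
        if self.spec.t2_mode is None:
            return
        flag, lead = detect_t2_only(traj, self.tl)
        traj.t2_only_progression = flag
        traj.t2_lead_months = lead


def detect_t2_only(traj: CriterionTrajectory, tl: PatientTimeline):
    """T2/FLAIR progression preceding (or occurring without) enhancing
    progression, with the lead time in months.

    Uses the per-scan rule-firing flags of a T2-aware trajectory. The lead
    is measured from the first T2-firing scan to the first CE-firing scan;
    if enhancing progression never occurs, the lead spans the remaining
    follow-up. Simultaneous firing is not T2-only.
    """
    t2_first = next(
        (i for i, f in enumerate(traj.t2_progression_flags) if f), None
    )
    ce_first = next(
        (i for i, f in enumerate(traj.ce_progression_flags) if f), None
    )
    if t2_first is None:
        return False, None
    if ce_first is not None and ce_first <= t2_first:
        return False, None
    t2_date = traj.scan_dates[t2_first]
    end_date = (
        traj.scan_dates[ce_first] if ce_first is not None else traj.scan_dates[-1]
    )
    return True, months_between(t2_date, end_date)


# ---------------------------------------------------------------------------
# Public assessors


def assess_macdonald(
    tl: PatientTimeline,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
    cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS,
) -> CriterionTrajectory:
    """MacDonald read: 2D enhancing rules, no T2, no confirmation."""
    return _Engine(tl, th, _SPECS[Criterion.MACDONALD], cutoffs).run()


def assess_rano(
    tl: PatientTimeline,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
    cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS,
) -> CriterionTrajectory:
    """RANO read: 2D enhancing rules plus the 2D T2/FLAIR compartment."""
    return _Engine(tl, th, _SPECS[Criterion.RANO], cutoffs).run()


def assess_vol_rano(
    tl: PatientTimeline,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
    cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS,
) -> CriterionTrajectory:
    """Vol-RANO read: volumetric enhancing rules plus volumetric T2."""
    return _Engine(tl, th, _SPECS[Criterion.VOL_RANO], cutoffs).run()


def assess_mrano(
    tl: PatientTimeline,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
    dims: str = "d2",
    cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS,
) -> CriterionTrajectory:
    """mRANO read (``dims='d2'``) or Vol-mRANO (``dims='d3'``):
    enhancing-only rules with the confirmation-scan cycle."""
    if dims not in ("d2", "d3"):
        raise ValueError("dims must be 'd2' or 'd3'")
    crit = Criterion.MRANO if dims == "d2" else Criterion.VOL_MRANO
    return _Engine(tl, th, _SPECS[crit], cutoffs).run()


def assess_irano(
    tl: PatientTimeline,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
    immunotherapy_start: Optional[_dt.date] = None,
    cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS,
) -> CriterionTrajectory:
    """iRANO read; requires an immunotherapy start date (vaccine arm)."""
    start = immunotherapy_start or tl.immunotherapy_start
    if start is None:
        raise CriterionInapplicableError(
            f"patient {tl.patient_id}: iRANO requires an immunotherapy start date"
        )
    return _Engine(
        tl, th, _SPECS[Criterion.IRANO], cutoffs, immunotherapy_start=start
    ).run()


_ASSESSORS = {
    Criterion.MACDONALD: assess_macdonald,
    Criterion.RANO: assess_rano,
    Criterion.VOL_RANO: assess_vol_rano,
    Criterion.MRANO: lambda tl, th=DEFAULT_THRESHOLDS, cutoffs=DEFAULT_CUTOFFS:
        assess_mrano(tl, th, "d2", cutoffs),
    Criterion.VOL_MRANO: lambda tl, th=DEFAULT_THRESHOLDS, cutoffs=DEFAULT_CUTOFFS:
        assess_mrano(tl, th, "d3", cutoffs),
    Criterion.IRANO: lambda tl, th=DEFAULT_THRESHOLDS, cutoffs=DEFAULT_CUTOFFS:
        assess_irano(tl, th, cutoffs=cutoffs),
}


def assess(
    tl: PatientTimeline,
    criterion: Criterion,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
    cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS,
) -> CriterionTrajectory:
    """Run one criterion's engine on one patient."""
    return _ASSESSORS[criterion](tl, th, cutoffs)


def assess_all(
    tl: PatientTimeline,
    th: CriterionThresholds = DEFAULT_THRESHOLDS,
    criteria=None,
    cutoffs: MeasurabilityCutoffs = DEFAULT_CUTOFFS,
    skip_inapplicable: bool = True,
) -> dict[Criterion, CriterionTrajectory]:
    """All requested criteria for one patient; iRANO is skipped (not an
    error) for patients without immunotherapy when ``skip_inapplicable``."""
    from .cohort_model import CRITERION_ORDER

    out = {}
    for crit in criteria or CRITERION_ORDER:
        try:
            out[crit] = assess(tl, crit, th, cutoffs)
        except CriterionInapplicableError:
            if not skip_inapplicable:
                raise
    return out
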