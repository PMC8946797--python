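"""Seeded generator of virtual glioblastoma trial patients.

Emulates the study conditions every other stage is tested against: a
pre-surgery diagnosis date, gross total resection with a non-measurable
post-op baseline, first follow-up MRI 10 +/- 2 weeks after the start of
radiochemotherapy and further scans every 3 months +/- 2 weeks, latent
progression/death times, pseudoprogression episodes (transient enhancing
lesions at the first or second follow-up that regress on the next scan),
T2-only progression (T2/FLAIR growth with delayed enhancing appearance),
loss to follow-up, and study-closure censoring.

The latent model: true progression is Weibull; death is progression plus
a lognormal post-progression survival draw whose scale is calibrated
once per configuration so the latent overall-survival median equals
``os_median``. Enhancing volume is zero until progression onset, then
grows exponentially with the configured doubling time; diameters derive
from volume through a sphere-equivalent diameter with mild anisotropy;
T2/FLAIR volume is stable until progression, then grows with the same
doubling time. All measurements carry multiplicative lognormal noise and
diameters are rounded to whole millimetres.

Every random draw flows from ``SimulationConfig.seed`` through one
``SeedSequence``; each patient has an index-keyed sub-stream, so adding
patients never perturbs earlier ones.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_model import (
    DAYS_PER_MONTH,
    Arm,
    LesionMeasurement,
    PatientTimeline,
    ScanRecord,
    VitalStatus,
)

__all__ = ["SimulationConfig", "LatentTruth", "SimulatedCohort",
           "simulate_patient", "simulate_cohort", "latent_to_frame"]


class Attrition(str, enum.Enum):
    NONE = "none"
    LTFU = "ltfu"
    ALIVE_AT_CLOSURE = "alive_at_closure"


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters (defaults are the emulated study conditions).

    Cohort anchors: 76 patients, 36 of them on the vaccine arm, latent
    median OS 19 months, ~10/76 lost to follow-up. Phenotype rates:
    pseudoprogression probability 0.30, T2-only probability 0.20, with
    the T2-to-enhancing lag drawn from 2-12 months. Scan schedule: first
    follow-up 10 +/- 2 weeks after radiochemotherapy start (itself fixed
    4 weeks after surgery), then every 3 +/- 0.5 months; vaccine-arm
    immunotherapy starts in week 7.
    """

    n_patients: int = 76
    arm_fraction_vaccine: float = 36 / 76
    os_median: float = 19.0            # months, latent OS median after calibration
    os_shape: float = 0.55             # lognormal sigma of the PPS component
    prog_median: float = 7.0           # months, Weibull median of true progression
    prog_shape: float = 1.4            # Weibull k
    pps_median: float = 10.0           # months, pre-calibration PPS median
    growth_doubling: float = 1.5       # months, CE/T2 volume doubling time
    initial_ce_volume: float = 0.5     # cm^3 at enhancing onset
    psp_prob: float = 0.30
    psp_bump_range: tuple[float, float] = (1.5, 3.0)   # cm^3 transient lesion
    t2only_prob: float = 0.20
    t2_ce_lag: tuple[float, float] = (2.0, 12.0)       # months
    measurement_cv: float = 0.10
    ltfu_prob: float = 10 / 76
    first_fu_weeks: tuple[float, float] = (10.0, 2.0)  # mean +/- half-range
    fu_interval_months: tuple[float, float] = (3.0, 0.5)
    seed: int = 0
    # placement constants
    rct_start_weeks: float = 4.0       # radiochemotherapy start after surgery
    immuno_start_weeks: float = 7.0    # vaccine start after surgery
    accrual_months: float = 24.0
    closure_months: float = 60.0       # study closure after first accrual
    t2_baseline_median: float = 8.0    # cm^3 residual T2/FLAIR load post-op
    t2_baseline_sigma: float = 0.5
    psp_t2_factor: tuple[float, float] = (1.4, 2.2)
    study_start: _dt.date = _dt.date(2011, 1, 1)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for p in (self.arm_fraction_vaccine, self.psp_prob, self.t2only_prob,
                  self.ltfu_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for v in (self.os_median, self.prog_median, self.pps_median,
                  self.growth_doubling, self.initial_ce_volume):
            if v <= 0:
                raise ValueError("scales and medians must be positive")


@dataclass
class LatentTruth:
    """Hidden ground truth behind one synthetic patient."""

    patient_id: str
    true_prog_months: float
    true_death_months: float
    had_psp_episode: bool
    psp_scan_index: int              # follow-up index of the episode, -1 if none
    is_t2_only: bool                 # T2 firing scan strictly precedes CE scan
    t2_lead_months: float            # 0 when not T2-only
    attrition: Attrition


@dataclass
class SimulatedCohort:
    timelines: list[PatientTimeline]
    truths: list[LatentTruth]
    study_closure: _dt.date
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Latent-model helpers

_CALIBRATION_SEED = 202_020
_CALIBRATION_N = 40_000


def _weibull_scale(median: float, k: float) -> float:
    return median / math.log(2.0) ** (1.0 / k)


@lru_cache(maxsize=32)
def _pps_scale(prog_median: float, prog_shape: float, pps_median: float,
               os_shape: float, os_median: float) -> float:
    """Scale factor on the PPS component so the latent OS median equals
    ``os_median``; found by bisection on a fixed internal quadrature
    sample (independent of the cohort seed)."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    prog = rng.weibull(prog_shape, _CALIBRATION_N) * _weibull_scale(
        prog_median, prog_shape
    )
    pps = rng.lognormal(math.log(pps_median), os_shape, _CALIBRATION_N)
    lo, hi = 1e-3, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.median(prog + mid * pps) < os_median:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _date_at(origin: _dt.date, months: float) -> _dt.date:
    return origin + _dt.timedelta(days=round(months * DAYS_PER_MONTH))


def _sphere_diam_mm(volume_cm3: float) -> float:
    """Sphere-equivalent diameter (mm) of a volume in cm^3."""
    return 10.0 * 2.0 * (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def _sphere_area_mm2(volume_cm3: float) -> float:
    """Great-circle cross-section area (mm^2) of a sphere of given volume."""
    r_cm = (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return math.pi * r_cm * r_cm * 100.0


# ---------------------------------------------------------------------------


def simulate_patient(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "P0001",
    arm: Arm = Arm.SOC,
    accrual_offset_months: Optional[float] = None,
) -> tuple[PatientTimeline, LatentTruth]:
    """Draw one patient's latent course, scan schedule and measurements.

    Times below are months since diagnosis (pre-surgery MRI).
    """
    noise = (lambda: math.exp(rng.normal(0.0, cfg.measurement_cv))
             if cfg.measurement_cv > 0 else 1.0)
    if accrual_offset_months is None:
        accrual_offset_months = rng.uniform(0.0, cfg.accrual_months)
    diagnosis = _date_at(cfg.study_start, accrual_offset_months)
    closure_date = _date_at(cfg.study_start, cfg.closure_months)
    closure_m = (closure_date - diagnosis).days / DAYS_PER_MONTH

    surgery_m = 2.0 / DAYS_PER_MONTH
    postop_m = 3.0 / DAYS_PER_MONTH
    rct_m = surgery_m + cfg.rct_start_weeks * 7.0 / DAYS_PER_MONTH
    immuno_m = surgery_m + cfg.immuno_start_weeks * 7.0 / DAYS_PER_MONTH

    # latent event times
    prog_m = float(
        rng.weibull(cfg.prog_shape) * _weibull_scale(cfg.prog_median, cfg.prog_shape)
    )
    pps_scale = _pps_scale(cfg.prog_median, cfg.prog_shape, cfg.pps_median,
                           cfg.os_shape, cfg.os_median)
    pps_m = pps_scale * float(rng.lognormal(math.log(cfg.pps_median), cfg.os_shape))
    # floor: trial patients survive surgery + radiochemotherapy induction
    death_m = min(max(prog_m + pps_m, 2.0), 120.0)

    # phenotypes
    is_t2only_pheno = rng.uniform() < cfg.t2only_prob
    wants_psp = rng.uniform() < cfg.psp_prob
    ce_lag = float(rng.uniform(*cfg.t2_ce_lag)) if is_t2only_pheno else 0.0
    ce_start_m = prog_m + ce_lag

    # attrition draws
    ltfu_m = death_m * float(rng.uniform(0.3, 0.9)) if (
        rng.uniform() < cfg.ltfu_prob
    ) else math.inf

    # follow-up schedule
    mean_w, half_w = cfg.first_fu_weeks
    fu = rct_m + float(rng.uniform(mean_w - half_w, mean_w + half_w)) * 7.0 / DAYS_PER_MONTH
    horizon = min(death_m, ltfu_m, closure_m)
    fu_times: list[float] = []
    mean_i, half_i = cfg.fu_interval_months
    while fu < horizon and len(fu_times) < 40:
        fu_times.append(fu)
        fu += float(rng.uniform(mean_i - half_i, mean_i + half_i))
    if not fu_times:
        # died (or left) before the first scheduled follow-up: one terminal
        # scan shortly before the horizon so the series is assessable
        fu_times = [max(postop_m + 0.25, horizon - 0.3)]

    # pseudoprogression episode: transient lesion at FU1 or FU2, regressing
    # on the next scan; only instantiated when true progression falls after
    # the adjudication scan so the episode is unambiguously treatment-related
    psp_idx = -1
    psp_bump = 0.0
    if wants_psp:
        for cand in (0, 1):
            # the enhancing tumor must not yet be visible at the
            # adjudication scan, so the episode resolves as PsP
            if cand + 1 < len(fu_times) and ce_start_m > fu_times[cand + 1] + 0.2:
                psp_idx = cand
                psp_bump = float(rng.uniform(*cfg.psp_bump_range))
                break
    had_psp = psp_idx >= 0
    psp_t2_factor = float(rng.uniform(*cfg.psp_t2_factor)) if had_psp else 1.0

    t2_base = float(rng.lognormal(math.log(cfg.t2_baseline_median),
                                  cfg.t2_baseline_sigma))
    anisotropy = float(rng.uniform(1.0, 1.25))

    def ce_volume_true(t: float) -> float:
        if t < ce_start_m:
            return 0.0
        return min(cfg.initial_ce_volume * 2.0 ** ((t - ce_start_m) / cfg.growth_doubling),
                   150.0)

    def t2_volume_true(t: float) -> float:
        if t < prog_m:
            return t2_base
        return min(t2_base * 2.0 ** ((t - prog_m) / cfg.growth_doubling), 400.0)

    # build scans
    t2v_post = round(t2_base * noise(), 2)
    scans = [ScanRecord(
        scan_date=_date_at(diagnosis, postop_m),
        lesions=(),
        t2flair_volume=t2v_post,
        # 2D extent read off the same segmentation: no second noise draw
        t2flair_area=round(_sphere_area_mm2(t2v_post), 1),
        is_post_op=True,
    )]
    tumor_seen = False
    for i, t in enumerate(fu_times):
        lesions = []
        v = ce_volume_true(t)
        if v > 0:
            d = _sphere_diam_mm(v)
            lo = d * math.sqrt(anisotropy) * noise()
            pe = d / math.sqrt(anisotropy) * noise()
            lo, pe = max(lo, pe), min(lo, pe)
            lesions.append(LesionMeasurement(
                lesion_id="tumor-1",
                diam_longest=round(lo),
                diam_perp=round(pe),
                ce_volume=round(v * noise(), 3),
                is_new=not tumor_seen,
            ))
            tumor_seen = True
        if i == psp_idx:
            d = _sphere_diam_mm(psp_bump)
            lo = d * noise()
            pe = d / 1.05 * noise()
            lo, pe = max(lo, pe), min(lo, pe)
            lesions.append(LesionMeasurement(
                lesion_id="psp-lesion",
                diam_longest=round(lo),
                diam_perp=round(pe),
                ce_volume=round(psp_bump * noise(), 3),
                is_new=True,
            ))
        t2v = t2_volume_true(t) * (psp_t2_factor if i == psp_idx else 1.0)
        t2v_meas = round(t2v * noise(), 2)
        scans.append(ScanRecord(
            scan_date=_date_at(diagnosis, t),
            lesions=tuple(lesions),
            t2flair_volume=t2v_meas,
            t2flair_area=round(_sphere_area_mm2(t2v_meas), 1),
            is_post_op=False,
        ))

    # vital status / last contact
    if ltfu_m < min(death_m, closure_m):
        status = VitalStatus.LOST_TO_FOLLOW_UP
        last_contact = _date_at(diagnosis, ltfu_m)
        attrition = Attrition.LTFU
    elif death_m <= closure_m:
        status = VitalStatus.DEAD
        last_contact = _date_at(diagnosis, death_m)
        attrition = Attrition.NONE
    else:
        status = VitalStatus.ALIVE_AT_CLOSURE
        last_contact = closure_date
        attrition = Attrition.ALIVE_AT_CLOSURE

    tl = PatientTimeline(
        patient_id=patient_id,
        arm=arm,
        diagnosis_date=diagnosis,
        scans=tuple(scans),
        immunotherapy_start=(
            _date_at(diagnosis, immuno_m) if arm is Arm.SOC_PLUS_VACCINE else None
        ),
        reresection_date=None,
        last_contact_date=last_contact,
        vital_status=status,
    )

    # ground-truth T2-only phenotype at scan resolution: the scan first
    # showing a doubled T2 load must strictly precede the scan first
    # showing the enhancing lesion
    t2_cross_m = prog_m + cfg.growth_doubling
    t2_scan = next((t for t in fu_times if t >= t2_cross_m), None)
    ce_scan = next((t for t in fu_times if t >= ce_start_m), None)
    is_t2_only = bool(
        is_t2only_pheno and not had_psp and t2_scan is not None
        and (ce_scan is None or t2_scan < ce_scan)
    )
    t2_lead = 0.0
    if is_t2_only:
        t2_lead = (ce_scan if ce_scan is not None else fu_times[-1]) - t2_scan

    truth = LatentTruth(
        patient_id=patient_id,
        true_prog_months=prog_m,
        true_death_months=death_m,
        had_psp_episode=had_psp,
        psp_scan_index=psp_idx,
        is_t2_only=is_t2_only,
        t2_lead_months=t2_lead,
        attrition=attrition,
    )
    return tl, truth


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Simulate ``cfg.n_patients`` independent patients.

    Arm assignment is stratified-exact: round(arm_fraction_vaccine x n)
    patients receive the vaccine, chosen by a seeded permutation.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_patients + 1)
    arm_rng = np.random.default_rng(children[-1])
    n_vax = int(round(cfg.arm_fraction_vaccine * cfg.n_patients))
    vax_idx = set(arm_rng.permutation(cfg.n_patients)[:n_vax].tolist())
    timelines, truths = [], []
    width = max(4, len(str(cfg.n_patients)))
    for i in range(cfg.n_patients):
        rng = np.random.default_rng(children[i])
        arm = Arm.SOC_PLUS_VACCINE if i in vax_idx else Arm.SOC
        tl, truth = simulate_patient(cfg, rng, patient_id=f"P{i:0{width}d}", arm=arm)
        timelines.append(tl)
        truths.append(truth)
    closure = _date_at(cfg.study_start, cfg.closure_months)
    return SimulatedCohort(timelines, truths, closure, cfg)


def latent_to_frame(truths: list[LatentTruth]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": t.patient_id,
        "true_prog_months": t.true_prog_months,
        "true_death_months": t.true_death_months,
        "had_psp_episode": t.had_psp_episode,
        "psp_scan_index": t.psp_scan_index,
        "is_t2_only": t.is_t2_only,
        "t2_lead_months": t.t2_lead_months,
        "attrition": t.attrition.value,
    } for t in truths])
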