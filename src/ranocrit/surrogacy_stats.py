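"""Surrogate-endpoint comparison battery.

Rank comparison of PFS/PPS distributions across criteria
(Kruskal-Wallis omnibus + Dunn-type pairwise z tests with Bonferroni
family-wise adjustment), Spearman PFS-OS correlation, Kaplan-Meier
medians with confidence intervals, landmark Cox analysis of residual
survival by progression status, and pseudoprogression / T2-only
phenotype summaries.

Notes on fidelity to the source procedure: the across-criteria rank test
treats the per-criterion PFS vectors as independent samples even though
they are paired within patients (a paired Friedman-type variant is
offered); the Spearman correlation is computed on recorded times,
ignoring censoring indicators. Both choices replicate the published
procedure and carry a logged caveat.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from .cohort_model import Criterion, CriterionTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "KMEstimate",
    "CriteriaComparison",
    "LandmarkSummary",
    "km_median",
    "compare_pfs_across_criteria",
    "spearman_pfs_os",
    "landmark_summary",
    "landmark_analysis",
    "summarize_phenotypes",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMEstimate:
    """Kaplan-Meier median with 95% CI (log(-log) / exponential-Greenwood
    interval). ``defined`` is False when the survival curve never reaches
    0.5, in which case median and CI bounds may be None/inf."""

    median: Optional[float]
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    n: int
    n_events: int
    defined: bool


def km_median(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Kaplan-Meier median survival with 95% confidence interval.

    Requires at least one event; the median is undefined (flagged) when
    the curve never drops to 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0 or not events.any():
        return KMEstimate(None, None, None, int(times.size), 0, False)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    med = kmf.median_survival_time_
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    defined = np.isfinite(med)
    return KMEstimate(
        median=float(med) if defined else None,
        ci_lower=lo if np.isfinite(lo) else None,
        ci_upper=hi if np.isfinite(hi) else None,
        n=int(times.size),
        n_events=int(events.sum()),
        defined=bool(defined),
    )


# ---------------------------------------------------------------------------
# Across-criteria rank comparison


@dataclass
class CriteriaComparison:
    statistic: float
    p_omnibus: float
    pairwise_p: pd.DataFrame      # symmetric, unit diagonal, Bonferroni-capped
    pairwise_p_raw: pd.DataFrame
    method: str
    degenerate: bool = False


def _dunn_pairwise(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests (tie-corrected), raw p-values."""
    names = list(samples)
    pooled = np.concatenate([samples[n] for n in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction on the pooled ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes, pos = {}, {}, 0
    for name in names:
        k = samples[name].size
        mean_ranks[name] = ranks[pos:pos + k].mean()
        sizes[name] = k
        pos += k
    out = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        out.loc[a, b] = out.loc[b, a] = p
    return out


def _mannwhitney_pairwise(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(samples)
    out = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        p = stats.mannwhitneyu(samples[a], samples[b]).pvalue
        out.loc[a, b] = out.loc[b, a] = p
    return out


def compare_pfs_across_criteria(
    times_by_criterion: Mapping, posthoc: str = "dunn", paired: bool = False
) -> CriteriaComparison:
    """Omnibus rank test + Bonferroni-adjusted pairwise matrix.

    ``times_by_criterion`` maps criterion name to a vector of per-patient
    times (PFS or PPS, months). ``posthoc`` selects Dunn-type z tests
    (default) or pairwise Mann-Whitney; ``paired=True`` swaps the
    Kruskal-Wallis omnibus for a Friedman test (requires equal-length,
    patient-aligned vectors).
    """
    samples = {
        (k.value if isinstance(k, Criterion) else str(k)): np.asarray(v, float)
        for k, v in times_by_criterion.items()
    }
    if len(samples) < 2:
        raise ValueError("need at least two criteria to compare")
    if any(v.size < 2 for v in samples.values()):
        raise ValueError("need at least two observations per criterion")
    pooled = np.concatenate(list(samples.values()))
    names = list(samples)
    m = len(names) * (len(names) - 1) // 2
    if np.ptp(pooled) == 0:
        logger.warning("all times identical across criteria; comparison degenerate")
        unit = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                            columns=names)
        return CriteriaComparison(0.0, 1.0, unit, unit.copy(),
                                  method="degenerate", degenerate=True)
    if paired:
        stat, p = stats.friedmanchisquare(*samples.values())
        method = "friedman+" + posthoc
    else:
        stat, p = stats.kruskal(*samples.values())
        method = "kruskal-wallis+" + posthoc
    raw = (_dunn_pairwise if posthoc == "dunn" else _mannwhitney_pairwise)(samples)
    adj = (raw * m).clip(upper=1.0)
    np.fill_diagonal(adj.values, 1.0)
    return CriteriaComparison(float(stat), float(p), adj, raw, method=method)


def spearman_pfs_os(
    pfs_months: Sequence[float], os_months: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between PFS and OS times.

    Censored times enter as recorded. Raises on zero variance in either
    margin (correlation undefined).
    """
    x = np.asarray(pfs_months, float)
    y = np.asarray(os_months, float)
    if x.size < 3:
        raise ValueError("need at least three (PFS, OS) pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman correlation undefined")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Landmark analysis


@dataclass
class LandmarkSummary:
    """Residual-survival hazard analysis at one landmark for one criterion.

    Patients dead (or out of observation) before the landmark are
    excluded; status is PD when progression occurred at or before the
    landmark, SD otherwise; the Cox fit regresses residual survival
    (from the landmark) on that status. Medians are reported on the OS
    scale (landmark + residual median).
    """

    criterion: str
    landmark_months: float
    n_included: int
    n_pd: int
    n_sd: int
    hazard_ratio: Optional[float]
    hr_ci: tuple[Optional[float], Optional[float]]
    p_value: Optional[float]
    median_os_sd: Optional[KMEstimate]
    median_os_pd: Optional[KMEstimate]
    applicable: bool


def landmark_summary(
    df: pd.DataFrame, landmark_months: float, criterion: str = ""
) -> LandmarkSummary:
    """Landmark analysis for one criterion.

    ``df`` needs columns pfs_months, pfs_event, os_months, os_event (one
    row per patient).
    """
    if landmark_months <= 0:
        raise ValueError("landmark must be positive")
    sub = df[df["os_months"] > landmark_months].copy()
    sub["pd_status"] = (
        sub["pfs_event"].astype(bool) & (sub["pfs_months"] <= landmark_months)
    ).astype(int)
    sub["residual"] = sub["os_months"] - landmark_months
    n_pd = int(sub["pd_status"].sum())
    n_sd = int(len(sub) - n_pd)
    if n_pd == 0 or n_sd == 0 or sub["os_event"].sum() == 0:
        return LandmarkSummary(criterion, landmark_months, len(sub), n_pd, n_sd,
                               None, (None, None), None, None, None, False)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(sub[["residual", "os_event", "pd_status"]],
                duration_col="residual", event_col="os_event")
    hr = float(np.exp(cph.params_["pd_status"]))
    ci = cph.confidence_intervals_.loc["pd_status"]
    hr_ci = (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])))
    p = float(cph.summary.loc["pd_status", "p"])

    def _group_median(mask):
        g = sub[mask]
        est = km_median(g["residual"], g["os_event"].astype(bool))
        if est.median is None:
            return est
        # report on the overall-survival scale
        shift = lambda v: None if v is None else v + landmark_months
        return KMEstimate(shift(est.median), shift(est.ci_lower),
                          shift(est.ci_upper), est.n, est.n_events, est.defined)

    return LandmarkSummary(
        criterion=criterion,
        landmark_months=landmark_months,
        n_included=int(len(sub)),
        n_pd=n_pd,
        n_sd=n_sd,
        hazard_ratio=hr,
        hr_ci=hr_ci,
        p_value=p,
        median_os_sd=_group_median(sub["pd_status"] == 0),
        median_os_pd=_group_median(sub["pd_status"] == 1),
        applicable=True,
    )


def landmark_analysis(
    endpoints: pd.DataFrame, landmark_months: float
) -> list[LandmarkSummary]:
    """Landmark summaries per criterion from a tidy endpoint table
    (columns: criterion, pfs_months, pfs_event, os_months, os_event)."""
    out = []
    for crit, sub in endpoints.groupby("criterion", sort=False):
        out.append(landmark_summary(sub, landmark_months, criterion=str(crit)))
    return out


def landmark_frame(summaries: Iterable[LandmarkSummary]) -> pd.DataFrame:
    """Hazard-ratio table, one row per (criterion, landmark)."""
    rows = []
    for s in summaries:
        rows.append({
            "criterion": s.criterion,
            "landmark_months": s.landmark_months,
            "n_included": s.n_included,
            "n_pd": s.n_pd,
            "hazard_ratio": s.hazard_ratio,
            "hr_ci_lower": s.hr_ci[0],
            "hr_ci_upper": s.hr_ci[1],
            "p_value": s.p_value,
            "median_os_sd": s.median_os_sd.median if s.median_os_sd else None,
            "median_os_pd": s.median_os_pd.median if s.median_os_pd else None,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phenotype summaries


def summarize_phenotypes(
    trajectories: Mapping[str, Mapping[Criterion, CriterionTrajectory]],
    endpoints: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-criterion pseudoprogression and T2-only progression tallies.

    Returns one row per criterion with PsP count/fraction, T2-only
    count/fraction, median T2 lead (months), and — when an endpoint table
    is supplied — Kaplan-Meier median OS for patients with and without
    confirmed PsP.
    """
    per_crit: dict[Criterion, list[CriterionTrajectory]] = {}
    for per_patient in trajectories.values():
        for crit, traj in per_patient.items():
            per_crit.setdefault(crit, []).append(traj)
    os_by_pid = {}
    if endpoints is not None:
        first = endpoints.drop_duplicates("patient_id")
        os_by_pid = {
            r["patient_id"]: (r["os_months"], bool(r["os_event"]))
            for r in first.to_dict("records")
        }
    rows = []
    for crit, trajs in per_crit.items():
        n = len(trajs)
        psp = [t for t in trajs if t.psp_confirmed]
        t2only = [t for t in trajs if t.t2_only_progression]
        leads = [t.t2_lead_months for t in t2only if t.t2_lead_months is not None]
        row = {
            "criterion": crit.value,
            "n": n,
            "psp_count": len(psp),
            "psp_fraction": len(psp) / n if n else np.nan,
            "t2_only_count": len(t2only),
            "t2_only_fraction": len(t2only) / n if n else np.nan,
            "median_t2_lead_months": float(np.median(leads)) if leads else np.nan,
            "median_os_psp": np.nan,
            "median_os_no_psp": np.nan,
        }
        if os_by_pid:
            psp_ids = {t.patient_id for t in psp}
            for key, ids in (("median_os_psp", psp_ids),
                             ("median_os_no_psp",
                              {t.patient_id for t in trajs} - psp_ids)):
                pairs = [os_by_pid[p] for p in ids if p in os_by_pid]
                if pairs:
                    est = km_median([p[0] for p in pairs], [p[1] for p in pairs])
                    row[key] = est.median if est.median is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
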