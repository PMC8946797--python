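import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ranocrit as rc
from ranocrit.surrogacy_stats import (
    compare_pfs_across_criteria,
    km_median,
    landmark_analysis,
    landmark_summary,
    spearman_pfs_os,
    summarize_phenotypes,
)


class TestCompareAcrossCriteria:
    def test_identical_samples_are_degenerate_with_unit_pvalues(self):
        same = {"a": [5.0] * 10, "b": [5.0] * 10}
        out = compare_pfs_across_criteria(same)
        assert out.degenerate and out.p_omnibus == 1.0
        assert (out.pairwise_p.values == 1.0).all()

    def test_disjoint_supports_are_clearly_separated(self):
        rng = np.random.default_rng(3)
        grp = {
            "short": rng.uniform(1, 4, 20),
            "long": rng.uniform(10, 14, 20),
        }
        out = compare_pfs_across_criteria(grp)
        assert out.p_omnibus < 0.01
        assert out.pairwise_p.loc["short", "long"] < 0.01

    def test_bonferroni_adjustment_bounds(self):
        rng = np.random.default_rng(8)
        grp = {k: rng.exponential(7, 30) for k in "abcd"}
        out = compare_pfs_across_criteria(grp)
        adj, raw = out.pairwise_p, out.pairwise_p_raw
        assert (adj.values >= raw.values - 1e-12).all()
        assert (adj.values <= 1.0).all()
        assert np.allclose(adj.values, adj.values.T)
        assert np.allclose(np.diag(adj.values), 1.0)

    def test_dunn_z_matches_direct_construction_without_ties(self):
        # independent check: untied two-group Dunn z equals the normal
        # approximation of the Mann-Whitney statistic on pooled ranks
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 12)
        out = compare_pfs_across_criteria({"a": a, "b": b})
        n1, n2 = len(a), len(b)
        n = n1 + n2
        ranks = stats.rankdata(np.concatenate([a, b]))
        z = (ranks[:n1].mean() - ranks[n1:].mean()) / math.sqrt(
            n * (n + 1) / 12 * (1 / n1 + 1 / n2))
        expected = 2 * stats.norm.sf(abs(z))
        assert out.pairwise_p_raw.loc["a", "b"] == pytest.approx(expected)

    def test_pairwise_mannwhitney_option(self):
        rng = np.random.default_rng(5)
        grp = {"a": rng.normal(0, 1, 15), "b": rng.normal(2, 1, 15)}
        out = compare_pfs_across_criteria(grp, posthoc="mannwhitney")
        direct = stats.mannwhitneyu(grp["a"], grp["b"]).pvalue
        assert out.pairwise_p_raw.loc["a", "b"] == pytest.approx(direct)


class TestSpearman:
    def test_monotone_and_antimonotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_pfs_os(x, [2.0, 3.0, 8.0, 20.0])[0] == 1.0
        assert spearman_pfs_os(x, [20.0, 8.0, 3.0, 2.0])[0] == -1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(5, 40)
        y = x + rng.normal(0, 1, 40)
        r1, _ = spearman_pfs_os(x, y)
        r2, _ = spearman_pfs_os(np.log1p(x), y**3)
        assert r1 == pytest.approx(r2)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(ValueError):
            spearman_pfs_os([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestKaplanMeierMedian:
    def test_equals_sample_median_without_censoring(self):
        est = km_median(np.arange(1.0, 10.0), np.ones(9, bool))
        assert est.median == 5.0
        assert est.defined and est.n_events == 9

    def test_recovers_exponential_median(self):
        rng = np.random.default_rng(12)
        lam = math.log(2) / 19.0
        times = rng.exponential(1 / lam, 2000)
        cens = rng.uniform(0, 200, 2000)
        observed = np.minimum(times, cens)
        events = times <= cens
        est = km_median(observed, events)
        assert est.ci_lower <= 19.0 <= est.ci_upper
        assert est.median == pytest.approx(19.0, rel=0.08)

    def test_undefined_when_curve_never_reaches_half(self):
        times = [1.0, 2.0, 10.0, 11.0, 12.0, 13.0]
        events = [True, True, False, False, False, False]
        est = km_median(times, events)
        assert not est.defined and est.median is None

    def test_no_events_flagged(self):
        est = km_median([5.0, 6.0], [False, False])
        assert not est.defined and est.n_events == 0


class TestLandmark:
    def test_patients_dead_before_landmark_are_excluded(self):
        df = pd.DataFrame({
            "pfs_months": [2.0, 3.0, 5.0, 6.0, 9.0, 1.0],
            "pfs_event": [True, True, True, False, False, True],
            "os_months": [3.0, 12.0, 14.0, 15.0, 16.0, 17.0],
            "os_event": [True, True, True, True, False, True],
        })
        s = landmark_summary(df, 4.0)
        assert s.n_included == 5          # first patient died at month 3
        # progressed at/before month 4: the pfs=3 and pfs=1 patients
        assert s.n_pd == 2 and s.n_sd == 3

    def test_empty_status_group_is_inapplicable(self):
        df = pd.DataFrame({
            "pfs_months": [9.0, 10.0, 11.0],
            "pfs_event": [False, False, False],
            "os_months": [12.0, 13.0, 14.0],
            "os_event": [True, True, True],
        })
        s = landmark_summary(df, 4.0)
        assert not s.applicable and s.hazard_ratio is None

    def test_hr_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(6)
        n = 300
        status = rng.random(n) < 0.5
        res = rng.exponential(np.where(status, 6.0, 12.0))
        df = pd.DataFrame({
            "pfs_months": np.where(status, 2.0, 50.0),
            "pfs_event": status,
            "os_months": 4.0 + res,
            "os_event": True,
        })
        s1 = landmark_summary(df, 4.0)
        df2 = df.copy()
        df2[["pfs_months", "os_months"]] *= 30.4375   # months -> days
        s2 = landmark_summary(df2, 4.0 * 30.4375)
        assert s1.hazard_ratio == pytest.approx(s2.hazard_ratio, rel=1e-6)

    def test_per_criterion_table_shape(self):
        rng = np.random.default_rng(13)
        frames = []
        for crit in ("MacDonald", "mRANO"):
            n = 120
            status = rng.random(n) < 0.5
            frames.append(pd.DataFrame({
                "criterion": crit,
                "pfs_months": np.where(status, 2.0, 40.0),
                "pfs_event": status,
                "os_months": 4.0 + rng.exponential(12.0, n),
                "os_event": True,
            }))
        out = landmark_analysis(pd.concat(frames), 4.0)
        assert [s.criterion for s in out] == ["MacDonald", "mRANO"]
        for s in out:
            assert s.applicable
            assert s.hr_ci[0] <= s.hazard_ratio <= s.hr_ci[1]


class TestPhenotypeSummary:
    def test_all_stable_cohort_has_zero_counts(self):
        cfg = rc.SimulationConfig(n_patients=25, seed=77, psp_prob=0.0,
                                  t2only_prob=0.0, measurement_cv=0.0,
                                  prog_median=200.0, closure_months=40.0)
        cohort = rc.simulate_cohort(cfg)
        trajs = {tl.patient_id: rc.assess_all(tl) for tl in cohort.timelines}
        out = summarize_phenotypes(trajs)
        assert (out["psp_count"] == 0).all()
        assert (out["t2_only_count"] == 0).all()

    def test_psp_and_t2_counts_match_trajectory_flags(self):
        cohort = rc.simulate_cohort(rc.SimulationConfig(n_patients=120, seed=4))
        trajs = {tl.patient_id: rc.assess_all(tl) for tl in cohort.timelines}
        recs = rc.cohort_endpoints(trajs, cohort.timelines,
                                   cohort.study_closure)
        out = summarize_phenotypes(trajs, rc.endpoints_frame(recs))
        row = out[out.criterion == "mRANO"].iloc[0]
        manual = sum(per[rc.Criterion.MRANO].psp_confirmed
                     for per in trajs.values())
        assert row.psp_count == manual
        assert row.psp_fraction == pytest.approx(manual / len(trajs))
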