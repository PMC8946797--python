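"""Simulate a virtual 76-patient glioblastoma trial cohort.

The generator reproduces the trial's structure: stratified arm
assignment (36 vaccine / 40 control), first follow-up MRI ~10 weeks
after radiochemotherapy then 3-monthly scans, latent progression and
death times with a 19-month median overall survival, pseudoprogression
episodes, T2-only progression, and loss to follow-up. The latent truth
behind every patient is returned alongside the measurements.
"""

import numpy as np

import ranocrit as rc
from ranocrit.surrogacy_stats import km_median

cfg = rc.SimulationConfig(n_patients=76, seed=42)
cohort = rc.simulate_cohort(cfg)

vax = sum(tl.arm is rc.Arm.SOC_PLUS_VACCINE for tl in cohort.timelines)
print(f"patients: {len(cohort.timelines)} ({vax} vaccine arm)")
print(f"study closure: {cohort.study_closure}")

truths = cohort.truths
print(f"pseudoprogression episodes: {sum(t.had_psp_episode for t in truths)} "
      f"({np.mean([t.had_psp_episode for t in truths]):.1%})")
print(f"T2-only progression: {sum(t.is_t2_only for t in truths)} "
      f"({np.mean([t.is_t2_only for t in truths]):.1%})")
print(f"lost to follow-up: "
      f"{sum(t.attrition.value == 'ltfu' for t in truths)}")

trajs = {tl.patient_id: {rc.Criterion.MACDONALD: rc.assess_macdonald(tl)}
         for tl in cohort.timelines}
df = rc.endpoints_frame(rc.cohort_endpoints(trajs, cohort.timelines,
                                            cohort.study_closure))
est = km_median(df.os_months, df.os_event.astype(bool))
print(f"Kaplan-Meier median OS: {est.median:.1f} months "
      f"(95% CI {est.ci_lower:.1f}-{est.ci_upper:.1f})")

n_scans = [len(tl.scans) - 1 for tl in cohort.timelines]
print(f"follow-up scans per patient: median {int(np.median(n_scans))} "
      f"(range {min(n_scans)}-{max(n_scans)})")
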