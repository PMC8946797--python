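# ranocrit

MRI response-assessment criteria for glioblastoma, as code: the six
longitudinal criteria in clinical use — **MacDonald**, **RANO**,
**Vol-RANO**, **mRANO**, **Vol-mRANO** and **iRANO** — implemented as
tested state machines over per-scan tumor measurements, together with
the survival machinery needed to ask which criterion's progression call
is the best surrogate for overall survival.

It is written for neuro-oncology imaging researchers and trial
statisticians who have longitudinal lesion measurements (perpendicular
diameters of contrast-enhancing disease, segmented contrast-enhancing
and T2/FLAIR volumes, new-lesion flags) and want reproducible,
auditable response labels and endpoint analyses rather than spreadsheet
reads.

## The criteria in brief

Per scan, disease burden is the sum over measurable lesions of the
bidimensional product *d*<sub>longest</sub> × *d*<sub>perp</sub>
(measurable: both diameters ≥ 1 cm) or the summed contrast-enhancing
volume (measurable: total ≥ 1 cm³). Against a post-operative baseline
(which resets to any later best-response scan) and the running nadir:

| criterion | PD | PR | extras |
|---|---|---|---|
| MacDonald | ≥ 25% product increase vs nadir, or new lesion | ≥ 50% product decrease | — |
| RANO | MacDonald PD, or significant (≥ 25%) T2/FLAIR area increase | ≥ 50% decrease, T2 stable/improved | T2/FLAIR compartment |
| Vol-RANO | ≥ 40% volume increase, or ≥ 100% T2/FLAIR volume increase | ≥ 65% volume decrease | volumetric |
| mRANO / Vol-mRANO | first crossing is *preliminary*; a further crossing on the next scan confirms PD, otherwise **pseudoprogression** is adjudicated and the baseline resets | confirmation cycle for PR too | confirmation scan |
| iRANO | RANO rules, but PD findings within 6 months of immunotherapy start require a confirming scan ≥ 3 months later | as RANO | immunotherapy window |

All thresholds are ≥ (ties cross) and every cutoff is configurable.
Endpoints follow trial conventions: PFS and OS from the pre-surgery MRI,
censoring at the last scan / last visit / study closure, re-resection
backdating, and post-progression survival PPS = OS − PFS on the event
subset. The surrogacy battery covers Kruskal–Wallis + Dunn/Bonferroni
rank comparison of PFS and PPS across criteria, Spearman PFS–OS
correlation, Kaplan–Meier medians with CIs, landmark Cox analysis, and
pseudoprogression / T2-only tallies. A seeded synthetic-cohort generator
produces virtual trial patients with known latent truth so every stage
is testable end to end.

## Worked example

```python
import ranocrit as rc
from ranocrit.surrogacy_stats import km_median, spearman_pfs_os

cohort = rc.simulate_cohort(rc.SimulationConfig(n_patients=300, seed=7))
trajs = {tl.patient_id: rc.assess_all(tl) for tl in cohort.timelines}
df = rc.endpoints_frame(rc.cohort_endpoints(trajs, cohort.timelines,
                                            cohort.study_closure))
for crit in ("MacDonald", "mRANO"):
    sub = df[df.criterion == crit]
    med = km_median(sub.pfs_months, sub.pfs_event.astype(bool)).median
    r, _ = spearman_pfs_os(sub.pfs_months, sub.os_months)
    print(crit, round(med, 1), round(r, 2))
```

prints (from `examples/03_compare_criteria.py`, which extends this to
all six criteria):

```
criterion      n  med PFS  med PPS  r(PFS,OS)
MacDonald    300      6.7     10.7       0.44
RANO         300      6.3     11.2       0.43
Vol-RANO     300      6.3     10.8       0.45
mRANO        300     12.2      9.1       0.70
Vol-mRANO    300     12.2      9.1       0.70
iRANO        142     10.0      9.1       0.62
```

Read: on a cohort with ~30% pseudoprogression episodes, the
immediate-call criteria are fooled into early progression dates — short
PFS, long post-progression survival, weak PFS–OS correlation. The
confirmation-based criteria wait one scan, adjudicate pseudoprogression,
and their progression dates track the latent disease course: longer
PFS, shorter PPS, and a markedly stronger PFS–OS correlation. That
ordering is the package's central reproducible behaviour.

The `examples/` directory has one short script per capability:
single-patient assessment, cohort simulation, criteria comparison,
landmark analysis, and threshold recovery.

## Command line

A thin CLI wraps the same functions:

```
ranocrit simulate --n 76 --seed 42 --out cohort/
ranocrit assess --cohort cohort/ --criteria all --out assessment/
ranocrit endpoints --cohort cohort/ --out endpoints/
ranocrit compare --endpoints endpoints/endpoints.csv --out comparison/
ranocrit landmark --endpoints endpoints/endpoints.csv --out landmark/
ranocrit report --cohort cohort/ --out report/
```

Interchange is long-format CSV with ISO dates (one row per patient,
scan, lesion, plus a per-patient table of clinical anchor dates); every
output directory gets a `manifest.json` recording command, settings and
seed.

## Scope

The package consumes measurements, not images: MRI acquisition,
segmentation and registration are out of scope, as are the
corticosteroid/clinical-status components of the criteria (radiology
only) and reader-variability modelling.
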