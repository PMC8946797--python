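# Methods

This note records the models, conventions and numerical choices behind
`ranocrit`, in the order the pipeline runs them: burden aggregation,
the criterion engines, endpoint derivation, the surrogacy statistics,
and the synthetic-cohort generator.

## Burden aggregation and units

Measurements are fixed-unit: diameters in mm, contrast-enhancing (CE)
and T2/FLAIR volumes in cm³, 2D T2/FLAIR extent in mm². The
bidimensional burden of a scan is the sum over lesions of
longest-diameter × perpendicular-diameter, restricted to lesions with
both diameters ≥ 1 cm (per-lesion measurability); sub-cutoff lesions
never contribute to the measurable sum, so removing one cannot change
it. Volumetric burden sums *all* lesion volumes, and volumetric
measurability is judged on the summed total against 1 cm³ — the 2D rule
is per lesion, the 3D rule is on the total, matching how the two
families of criteria state their cutoffs. No cap is placed on the
number of target lesions by default (a configurable cap exists); how to
combine multiple lesions' products is genuinely underdetermined in 2D
criteria practice, and the sum of products is used, flagged here as a
choice. A month is 30.4375 days (mean calendar month). Dates may be
`datetime.date` or, where sub-day resolution matters (boundary sweeps
of the iRANO timing rules), `datetime.datetime`.

## Criterion engines

All six criteria share one longitudinal frame:

* **Baseline** starts at the post-op scan and resets to any later scan
  showing strictly smaller disease (best response). "Smaller" is
  ordered on the enhancing metric; criteria with a T2 compartment break
  enhancing ties on the T2 measure, so a purely non-enhancing best
  response also resets the baseline (needed for courses whose disease
  is T2-only).
* **Nadir** is the running minimum burden since the current baseline,
  up to the previous scan.
* Progression thresholds compare to the nadir; response thresholds to
  the baseline. All rules are ≥, so exact threshold hits cross.
* Precedence on simultaneous signals: PD beats everything; CR beats PR
  beats SD. PR/CR require a measurable baseline — with a non-measurable
  post-op baseline (the gross-total-resection situation) the best
  attainable response is SD, and the engines can never emit PR/CR on
  such a course (property-tested).
* A confirmed PD is absorbing: later scans keep the PD label and the
  event date is fixed.

Criterion-specific layers:

* **MacDonald**: 2D rules only (25% / 50%), new lesion ⇒ PD, no
  confirmation.
* **RANO**: adds the T2/FLAIR compartment. The criteria's "significant
  increase" of non-enhancing disease is reader judgment; it is
  operationalized as a configurable fractional increase of the 2D
  T2/FLAIR extent, default 25% to mirror the enhancing 2D threshold, or
  a new T2 lesion. T2 improvement is the ratio-symmetric decrease
  (below reference/(1+f)). Missing T2 measurements degrade the call to
  "stable" with a logged warning rather than failing the criterion.
* **Vol-RANO**: volumetric enhancing rules (40% / 65%) and the ≥ 100%
  T2/FLAIR volume rule. Missing lesion volumes make volumetric criteria
  inapplicable for that patient (an error, not a silent skip).
* **mRANO / Vol-mRANO**: enhancing-only rules with a confirmation
  cycle. The first threshold crossing is a preliminary PD; the next
  available scan confirms (a further ≥ 25%/40% increase **relative to
  the preliminary-PD scan**, or a new measurable lesion) or adjudicates
  pseudoprogression, after which the reference baseline resets to the
  adjudication scan with nadir tracking thereafter. The criteria's
  4–8-week confirmation window is relaxed to "next available scan"
  because 3-monthly trial schedules cannot honour it; a strict-window
  option flags out-of-window confirmations instead. After a
  pseudoprogression adjudication, a subsequent threshold crossing
  against the reset reference is treated as confirmed PD outright: the
  reference is already an adjudicated-elevated burden, and demanding a
  second confirmation cycle would systematically push events past the
  end of follow-up on quarterly schedules. An unresolved preliminary PD
  at the end of follow-up is not an event. Preliminary PR/CR follows
  the analogous cycle (durable PR, or pseudoresponse when the
  confirming scan shows PD-level findings).
* **iRANO**: RANO rules with an immunotherapy clock starting at vaccine
  start (configurable). PD-level findings at most 6 months after
  immunotherapy start open a pending preliminary PD; the first scan
  ≥ 3 months after the preliminary scan decides — confirmed PD if
  RANO-PD findings are still met **against the reference frozen at the
  preliminary call**, else pseudoprogression (baseline resets).
  Whether the original criteria compare the confirming scan to the
  frozen reference or to the preliminary scan itself is ambiguous; the
  frozen-reference reading is the default because the published worked
  courses judge the confirming T2 change against the original baseline.
  Findings after the 6-month window, or before immunotherapy has
  started, progress immediately. A pending preliminary call is shown as
  `preliminary_PD` while findings persist.
* **Progression-date convention**: confirmed events backdate to the
  preliminary-PD scan by default (`backdate_progression=False` dates
  them at the confirming scan instead); both conventions are
  first-class.

T2-only progression is detected from the per-scan rule-firing record: a
course is T2-only when the T2 rule fires strictly before (or without)
any enhancing-rule firing; the lead time runs from the T2-firing scan
to the first enhancing-firing scan, or over the remaining follow-up
when enhancing progression never occurs.

The engines are validated against an independent naive re-evaluation
(recomputing every baseline, nadir and comparison from scratch at every
scan, with no shared code) on 1,000 random discretized timelines, and
their decision boundaries are recovered empirically by bisection.

## Endpoints

PFS and OS both originate at the pre-surgery MRI (diagnosis), even
though the response reference is the post-op scan; both dates are kept.
OS: death is an event at the death date; loss to follow-up censors at
the last visit; alive at closure censors at the closure date. PFS: the
(confirmed) progression date is the event; a re-resection without
earlier progression makes the last scan before re-resection the event
date (never later than the re-resection itself); otherwise the last
scan censors. The phrasing that a stable last scan is "used as date of
progression" is implemented as censoring — the standard reading — with
an explicit option to treat it as an event. PPS is defined only on the
progression-event subset as OS − PFS with the OS event indicator.

## Surrogacy statistics

* Across-criteria PFS/PPS comparison: Kruskal–Wallis omnibus followed
  by Dunn-type rank z tests with tie correction and Bonferroni
  family-wise adjustment capped at 1 (pairwise Mann–Whitney available
  as an option). The six per-patient PFS values are paired within
  patients but are compared as independent samples to replicate the
  published procedure; a Friedman-type paired omnibus is offered. An
  all-identical input is degenerate and reported as p = 1 with a flag.
* Spearman PFS–OS uses recorded times, ignoring censoring indicators —
  again the as-published procedure, with the limitation noted here; a
  censoring-aware analysis is deliberately out of scope.
* Kaplan–Meier medians and 95% CIs come from lifelines; the CI is the
  exponential-Greenwood (log(−log)) interval. The median is undefined
  (flagged, not faked) when the curve never reaches 0.5; under zero
  censoring it equals the sample median.
* Landmark analysis at 4 and 8 months: patients whose observation ends
  at or before the landmark are excluded; status is PD when the
  progression event falls at or before the landmark; residual survival
  from the landmark is regressed on status with a Cox model (Efron tie
  handling, lifelines default). Group medians are reported on the OS
  scale (landmark + residual median). The fit is checked for type-I
  calibration (~5% over 1,000 null replicates) and for recovering a
  simulated doubled hazard within its CI.

## Synthetic cohort generator

The generator emulates the trial conditions the analyses are aimed at;
it is a study-condition definition, not a tuning surface.

Latent model per patient: true progression is Weibull (median 7 months,
shape 1.4); death is progression plus a lognormal post-progression
component (pre-calibration median 10 months, sigma 0.55). The
post-progression component is rescaled by a constant, found once per
configuration by bisection on a fixed internal quadrature sample, so
the latent OS median equals `os_median` (default 19 months) exactly;
this is what makes the OS anchor a real parameter. Death is floored at
2 months (trial patients survive surgery and induction) and capped at
120.

Schedule: diagnosis (pre-surgery MRI), surgery 2 days later, post-op
scan at 48 h, radiochemotherapy 4 weeks after surgery, first follow-up
10 ± 2 weeks after that, then scans every 3 ± 0.5 months until death,
loss to follow-up or study closure (accrual over 24 months, closure at
60 months). Vaccine-arm patients (exactly round(36/76 × n), seeded
permutation) start immunotherapy in week 7 after surgery.

Measurements: CE volume is zero until progression onset, then grows
exponentially with a 1.5-month doubling time from 0.5 cm³; diameters
derive from volume via the sphere-equivalent diameter with a persistent
mild anisotropy (product preserved), are multiplied by lognormal noise
(CV 10%) and rounded to whole mm; volumes carry their own noise.
T2/FLAIR volume is stable at a lognormal baseline (~8 cm³ median) until
progression, then grows with the same doubling time; the 2D T2 extent
is computed from the measured (noisy) T2 volume rather than drawn with
a second independent noise, reflecting that both are read off the same
segmentation — an independent 10% area noise would make the 25%
"significant increase" rule fire spuriously at rates no reader would
produce.

Phenotypes: with probability 0.30 a pseudoprogression episode — a
transient new enhancing lesion of 1.5–3 cm³ (comfortably measurable)
with a transient T2 bump — appears at the first (or second) follow-up
and regresses on the next scan. The episode is only instantiated when
the enhancing tumor is not yet visible at the adjudication scan, so the
episode is unambiguously treatment-related and `had_psp_episode`
records exactly what happened; this conditioning means the realized
episode rate is below 0.30 (roughly the fraction of patients whose
progression falls after the second follow-up), which also reproduces
the clinical observation that adjudicated-PsP patients are those with
more favourable courses. With probability 0.20 a patient is a T2-only
progressor: T2 growth starts at progression but the enhancing lesion is
delayed by 2–12 months. The realized `is_t2_only` flag is computed from
schedule arithmetic alone (the scan first showing a doubled T2 load
must strictly precede the scan first showing the enhancing lesion,
and no pseudoprogression episode fired enhancing rules earlier), so
engine detection can be tested against an engine-independent truth.
Loss to follow-up hits with probability 10/76 at a uniform fraction
(0.3–0.9) of the death time; patients whose death falls after closure
are censored alive.

Randomness: one `SeedSequence` per cohort, spawned into per-patient
sub-streams keyed by patient index — adding patients never perturbs
earlier ones, and a fixed seed reproduces a cohort bit for bit.

What the generator does **not** emulate: reader variability and
consensus reads, multifocal disease beyond the episode lesion,
re-resection (the endpoint rule is implemented and tested on hand-built
timelines), treatment-effect differences between arms (the emulated
trial found none), corticosteroid effects, and any image-level process.
Passing tests on this cohort therefore demonstrate the correctness and
the qualitative surrogacy behaviour of the criteria machinery under a
plausible disease model — not quantitative agreement with any real
cohort's medians, which depend on real measurement and reader
processes.

## Problem sizes used in the checks

Oracle equivalence runs 1,000 random timelines; phenotype recovery uses
20 replicate cohorts of n = 400; the directional PFS/PPS/correlation
orderings use one n = 500 cohort; landmark null/recovery use n = 500
and the type-I calibration 1,000 replicates of n = 120. These sizes
give Monte-Carlo error comfortably below the effects being checked
(binomial half-widths ≈ 4.5 percentage points at n = 400; HR CI
half-widths ≈ 20% at n = 500).
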