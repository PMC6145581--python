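# Methods

`nsaidcc` implements a nested case-control (risk-set sampled) analysis of
ischemic stroke (IS) risk under time-varying NSAID exposure, together with a
synthetic claims generator that makes every stage testable end to end. This
note records the model, the conventions, the defaults and why, and what the
synthetic validation does and does not establish.

## Study design

**Cohort.** New users of any NSAID (ATC prefix `M01A`): adults (>= 18 years
at entry) with one enrollment span covering the 365 days before their first
qualifying dispensing, no NSAID dispensing in those 365 days, and no
malignant-cancer diagnosis (non-melanoma skin cancer excepted) in that year.
Entry is the qualifying dispensing day; a person failing at one dispensing
may qualify at a later one (first qualifying entry only, no re-entry after
interruption). Exit is the earliest of: study end (default window
1999-07-01 to 2010-12-31, configurable per database), first hospital IS
discharge diagnosis on/after entry, end of the covering enrollment span,
first malignant-cancer diagnosis, or death. Same-day ties resolve by the
fixed priority IS > death > cancer > disenrollment > study end. "12 months"
is operationalised as 365 days throughout: calendar-month arithmetic is
ambiguous, day counts are testable. An IS before entry does not exclude —
it becomes the stroke-history covariate; an IS on the entry day itself
counts as a case with index = entry.

**Exposure.** Each dispensing supplies a closed day interval: the recorded
prescribed duration if present, otherwise the quantity in defined daily
doses (DDD) at one DDD per day. Supplies of the same scope are stitched
into continuous-use episodes when the gap `next.start − prev.end` is
strictly below 14 days (overlaps always merge). At an index date, exposure
is *current* if a supply overlaps the index day or ended within the 14 days
before it (end in `[index−14, index−1]`); *recent* if the latest supply
ended 15–183 days before; *past* otherwise. The gap convention makes the
15-day recent lower bound exactly contiguous with current. Duration of
continuous use (categories `<7`, `7–29`, `30–89`, `>=90` days) is truncated
at the index date, since future supply cannot affect exposure duration at
the event. Subjects current on two or more substances carry a separate
"current, multiple NSAIDs" indicator and contribute to no single-substance
contrast. Coxibs are celecoxib, etoricoxib, lumiracoxib, rofecoxib and
valdecoxib; every other NSAID is a traditional NSAID (tNSAID).

**Sampling.** Cases are cohort members exiting with IS; the index date is
the event date. For each case, up to 100 controls (configurable) are drawn
uniformly without replacement from the risk set: same database and sex, age
at cohort entry within ±1 year, entered on or before the index date, and
still at risk strictly after it. A later case is eligible as a control
before its own index day; controls may recur across sets; sets with no
eligible control are logged and excluded from modelling. Under
incidence-density sampling the conditional odds ratio estimates the
incidence rate ratio.

**Covariates.** Diagnosis-type confounders and prior drug use are assessed
in `[entry−365, entry]`; concurrent co-medication in `[index−90, index−1]`
(acute treatments `[index−30, index−1]`). The index day itself is excluded
to avoid capturing treatment triggered by the event. The a-priori tier
(stroke, TIA, myocardial infarction, heart failure, atrial fibrillation,
diabetes, hyperlipidemia, hypertension, smoking; prior antihypertensive and
cardiac-glycoside use; concurrent lipid-modifying agents, aspirin in both
windows, anticoagulants, platelet-aggregation inhibitors) is always
retained; a candidate tier (further comorbidity, lifestyle proxies,
diuretics, nitrates, CYP2C9 inhibitors, glucocorticoids, hormonal therapy)
is subjected to backward elimination. Code lists are configuration; the
synthetic stream uses one sentinel code per concept, and lifestyle factors
(smoking, obesity, alcohol) are recorded-diagnosis proxies.

## Estimation

Each matched set has exactly one case, so the Breslow conditional
likelihood is exact (no ties):

    l(beta) = sum_s [ x_case,s · beta − log sum_{j in s} exp(x_j · beta) ].

Exposure state indicators (current per substance or per class, current
multiple, recent any) enter with past use of any NSAID as the absorbed
reference. The log likelihood is concave; it is maximised by Newton–Raphson
from `beta = 0` with step-halving, using the analytic gradient and observed
information, converging when the gradient's max norm falls below 1e-8
(at most 50 iterations). Columns without within-set variation are dropped
and reported as not estimable; unmatched sets are excluded with a logged
count; |beta| > 20 flags separation and the fit as non-converged. Standard
errors come from the inverse observed information; 95% intervals are Wald,
`exp(beta ± 1.959964·se)`. Backward elimination refits after removing, one
at a time, the candidate with the largest Wald p >= 0.05 (the stay level);
exposure and a-priori columns are never removed. The elimination criterion
and threshold are this package's choice — the procedure's name fixes
neither — and are recorded in the elimination trace. Stratified analyses
reuse the pooled model's retained covariates for comparability across
strata rather than re-running elimination per stratum, and keep a set only
if its case and at least one control fall in the stratum. Report tables
round percentages half-up to one decimal and odds ratios to two.

## Synthetic claims generator

The generator emulates multi-database claims: persons with one enrollment
span starting uniformly within the first ~5.5 years of the study window
(`enrollment_lag_max_days = 2000`) and ending at study end, geometric
disenrollment (rate 2e-4/day, mean span ~13 years) or death (5e-5/day);
sex split 0.5/0.5; ages 18–85 (uniform) at study start. NSAID use is
episodic: a per-day initiation probability (default 1e-3, i.e. roughly one
new treatment episode per ~3 years) starts a refill chain; each dispensing
supplies a pack (e.g. 20/30/60 DDD at one DDD per day), refills follow with
probability 0.6 after a uniform 1–13-day end-to-fill gap, and 30% of
dispensings carry a recorded duration (equal to the DDD-implied one). By
default each person keeps a single substance, which makes substance-level
truth attribution exact; a config switch allows per-chain substance
redraws to exercise the multiple-current machinery.

Chronic confounders are drawn once per person (e.g. diabetes 12%,
hypertension 25%, concurrent aspirin 15%), emit a diagnosis or dispensing
record at regular intervals while enrolled (so assessment windows detect
them with essentially perfect sensitivity), multiply the NSAID initiation
rate (confounding by indication: adjusted and crude estimates differ), and
multiply the IS hazard. The per-day IS probability is

    baseline(sex, age band) × exp(sum of confounder log RRs
                                  + exposure-state log RR of that day)

with the day's exposure state computed by the *same* episode algebra the
analysis uses — current (per substance), recent (any), or reference
(past/never). Default baseline hazards rise by age band (2e-6/day at 18–59
up to 4e-5/day at 80+, male ratio 1.3), roughly reproducing the strong age
gradient of IS incidence. Events are drawn exactly from the
piecewise-constant hazard via per-segment geometric draws; only the first
IS per person is emitted, as a hospital discharge diagnosis. Cancer,
non-melanoma skin cancer and death arrive as independent geometric
censoring streams with their own codes. Everything is driven by a single
seeded generator: identical config + seed yields byte-identical tables.
Configured probabilities are validated so no person-day event probability
can reach 1.

What the generator does **not** emulate: real terminologies (sentinel codes
stand in for harmonised code lists), dose heterogeneity within a substance,
over-the-counter use, within-person changes of confounder status after
baseline, recording gaps or miscoding, and database-specific coding
practices. Passing tests therefore demonstrate the pipeline's internal
correctness under a known data-generating process, not robustness to the
measurement problems of real claims data.

## Validation scenario and a design property worth knowing

The parameter-recovery study simulates 50,000 persons with a true
current-use rate ratio of 1.5 for diclofenac (all other exposure effects
null), confounding by indication through diabetes, hypertension and
concurrent aspirin, and 1:10 risk-set sampling; 200 replicates per arm
check that the adjusted 95% CI covers ln 1.5 at the nominal rate and that
the null variant rejects at the nominal 5%.

This scenario uses an age-flat baseline hazard (1.2e-5/day, the population
average of the banded default) on purpose. Sets are matched on age at
*cohort entry*, not attained age: members entering in different calendar
years differ in attained age at the shared index date, and recency of entry
correlates positively with current use (everyone is current immediately
after entry). With a steep attained-age hazard gradient this leaves
residual within-set confounding — a property of the matched design itself,
not of the estimator — which attenuates current-use contrasts. The
recovery study is meant to validate the estimator, so its generator removes
the residual-confounding channel; the default configuration keeps the
age-banded hazard, and analyses of such data inherit the design's residual
age confounding just as a real nested case-control with entry-age matching
would. Users studying strong age gradients should consider adding
attained-age terms to the adjusted model.

## Numerical and degenerate-input choices

* Time is whole days; all intervals closed on both ends; ISO-8601 dates on
  disk, integer day numbers in memory.
* Dispensings with neither a positive quantity nor a positive recorded
  duration are data errors, not silently dropped.
* `compute_exit` requires a study-end candidate; missing causes are simply
  absent.
* The Newton step solves against `info + 1e-12·I`; a singular information
  matrix falls back to least squares / pseudo-inverse.
* Wald p-values for columns with zero standard error are treated as 0
  (infinite z), so such candidates are never removed by elimination; an
  inestimable candidate leaves the model with p = NaN in the trace.
* Percent and OR rounding is decimal half-up (`round_half_up`), matching
  the usual table style, not banker's rounding.
* The sampler sorts the chosen control indices, so output order is
  deterministic given the seed and independent of RNG internals.

## Known limitations

* One enrollment span per person is generated (the cohort builder accepts
  many); re-entry after interruption is not modelled.
* The age-band hazard is looked up at segment start; a band crossing inside
  a segment bounded by other breakpoints is handled by explicit band-day
  breakpoints, but the fractional-year rounding of band-crossing days can
  shift a boundary by a day.
* Duration analysis recodes current use only at the any-NSAID scope.
* Pooling concatenates case-control sets across databases (one conditional
  likelihood), not a meta-analysis of per-database estimates.
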