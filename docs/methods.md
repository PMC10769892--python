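# Methods

## Analysis pipeline

### Follow-up windows

Entry for a diagnosed person is `max(diagnosis date, practice quality
start, registration + 6 calendar months, study start)`; exit is
`min(death, deregistration, practice's last collection, administrative
end)` (defaults 1989-01-01 and 2019-01-16). Counting exposed time only
from diagnosis excludes immortal time. Intervals are half-open
`[entry, exit)`; a death on the entry day is kept as a one-day interval
(whether or not the death is counted as an event, so the possible-deaths
toggle below changes event flags but never person-time). Deaths flagged
*possible* (identified from incident-style codes rather than a death
registration) censor follow-up without counting as events unless the
sensitivity switch `include_possible_deaths` is set.

### Exposure density sampling

For each diagnosed person entering the cohort, up to k = 10 comparison
participants are drawn uniformly without replacement from pool members who
share sex, birth **year** and practice, are registered (past the six-month
run-in) and under observation at the index date, and have neither an
exposure nor an ID diagnosis on or before it. They inherit the exposed
person's entry date. Matching on birth year rather than exact birth date
keeps matching pools non-degenerate at realistic practice sizes; the same
pool person may serve in sets at different index dates (standard risk-set
sampling). Sets with fewer than k eligible candidates are retained and the
shortfall recorded — matching here is a sampling device, not a
conditional-likelihood requirement. A comparison participant later
diagnosed is censored at their own diagnosis date and re-enters as exposed.

A person whose ID record begins after their autism diagnosis contributes to
the no-ID cohort from entry to the ID date (censored there) and to the
with-ID cohort from the ID date onward; each segment is matched at its own
start date. Recording of ID typically happens later than the first autism
record, so this rule assigns each person-day to the diagnostic state
actually recorded at the time.

### Lexis expansion

Each day of follow-up is assigned the person's completed age on that day
(the birthday counts toward the new age; a 29 February birthday falls on
1 March in non-leap years). Days before the 18th birthday are dropped; ages
above 100 pool into the open 100+ stratum. All splitting is integer-day
arithmetic — person-years (days/365.25) appear only at aggregation, so
person-time conservation is exact in days. A death is assigned to the
completed age on the last day lived (exit − 1 day): assigning it to the age
at the exit date itself would, when death falls exactly on a birthday,
place an event in a stratum holding none of that person's time.

### Poisson rate model

Stratum deaths are modelled as `D ~ Poisson(exp(β₀ + β₁·age + β₂·age²) ·
person-years)`, fitted by iteratively reweighted least squares with age
centred at 60 and scaled by 1/10 for conditioning (coefficients and
covariance are mapped back to the natural scale; the internal scaling is
invisible to callers). Strata with zero person-years are dropped;
zero-death strata are valid likelihood contributions and kept. A data set
whose every stratum has zero deaths, or a non-converged IRLS, raises an
explicit error rather than returning a degenerate fit.

Two rate-ratio estimators are implemented, as the printed headline ratios
could arise from either: **indirect standardisation** (expected deaths =
comparison crude rates × exposed person-time cell-by-cell over age × sex;
Byar's approximation for the 95% CI on the observed count) is the default
reported estimator, and a **model-based group effect** (joint Poisson
regression with exposure indicator, quadratic age, sex, Wald CI) is used
for the comorbidity-adjusted sensitivity analysis, with covariates frozen
at entry. Exposed cells without a comparison rate are dropped and reported.
All-zero covariate columns are dropped (they are vacuous and would make the
design singular), which also makes the adjusted estimator reduce exactly to
the unadjusted one when no covariate varies.

### Life table

From modelled rates m_x (ages 18–100): `q_x = m_x/(1 + (1−a_x) m_x)` with
a_x = 0.5 at all closed ages (deaths mid-year; the national-statistics
infant-age refinements are irrelevant at 18+), radix 100,000,
`d = l·q`, `L = l − 0.5·d`, open interval `L₁₀₀ = l₁₀₀/m₁₀₀` (constant
hazard beyond the cap), `T` the reverse cumulative sum and `e = T/l`. The
reported figure is total expected length of life at 18, `18 + e₁₈`. The
result is invariant to the radix. `q` is capped at 1 (relevant only for
extreme simulated draws with m > 2).

Confidence intervals: coefficient vectors are drawn from
`N(β̂, Σ̂)` independently per group (the matched design induces some
dependence between group fits, but no joint model is available), rates and
the life table are rebuilt per draw, and 2.5/97.5 percentiles are reported;
default 10,000 draws, deterministic given the seed. If a percentile
interval fails to bracket the point estimate, the estimate is flagged,
never silently reordered. This is a period life expectancy: a summary of
contemporary rates, not a forecast of any cohort's lifespan.

## Synthetic cohort generator

The generator emulates the data-generating context the analysis assumes:
multiple practices with their own data-quality windows, an adult age
structure (birth years 1910–2000), registration at ages 0–40, independent
exponential deregistration, administrative end of follow-up, a rare
diagnosed group, group-specific comorbidity prevalences, and
Gompertz–Makeham mortality `h(a) = λ + α·exp(βa)` multiplied by group, sex
and comorbidity hazard ratios. One root seed spawns child RNG streams per
practice, so enlarging the number of practices leaves earlier practices
byte-identical, and identical (config, seed) gives byte-identical tables.

**Calibration.** λ = 5×10⁻⁵, β = 0.09, and α = 2.8831907×10⁻⁵ make the
comparison group's total life expectancy at 18 exactly 83.0 years for
women (by quadrature of the survivor function); the male multiplier 1.3112
gives 80.0 years. λ is deliberately small so the log-hazard is close to —
but not exactly — quadratic in age: the downstream Poisson model is mildly
misspecified, as intended. Default group hazard ratios are 2.0 (diagnosed,
no ID) and 3.0 (diagnosed with ID); comorbidity flags (childhood onset,
so established before any adult entry) carry hazard ratios between 1.0 and
3.0 and are assigned independently given group, which gives the adjusted
analysis a real mediated pathway to remove.

**Diagnosis recording and underascertainment.** Exposure *type* is
Bernoulli (default prevalence 1/450) and drives the hazard for life. A
candidate recording date is drawn uniformly over the adult study window,
independent of survival; the diagnosis is recorded only if the person is
alive then. Drawing the recording date conditionally on being before death
would guarantee that everyone dying in-window is already diagnosed — a
length-biased selection that inflates post-entry death rates (we measured
SMR ≈ 2.8 under a true hazard ratio of 2 with that variant). Under the
independent mechanism the recorded-diagnosed fraction falls below the type
prevalence (people who die first are never recorded), and unrecorded
exposed-type people sit in the comparison pool — the same
underascertainment and exposure-misclassification structure the analysis
faces on real registers. Deaths are sampled conditional on survival to the
later of registration and study start (only people alive then appear in a
practice's records), via inverse-transform sampling of the cumulative
hazard (closed forms for the pure-exponential and pure-Gompertz cases,
bracketed bisection for the mixture).

**What the generator does not emulate.** Calendar trends in diagnostic
incidence (the real data's diagnosed cohort is strongly skewed toward young
people and recent years; here the adult diagnosis age is uniform so the
whole 18–100 range is exercised), dependence between comorbidities beyond
their common group, cause-specific mortality, and any time-varying hazard
beyond age. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated mechanism, not robustness to the
ascertainment dynamics of real registers.

## Validation studies and problem sizes

* **Full-scale recovery** (`validation.end_to_end_recovery`): 200,000
  persons, exposure-type prevalence 5%, no deregistration, comorbidity
  hazard ratios 1 and both group hazard ratios 2.0, so the marginal rate
  ratio equals 2.0 and comparison life expectancy is exactly the calibrated
  80/83. At this size the comparison groups carry ~4–5,000 deaths per sex,
  putting the Monte-Carlo standard error of e₁₈ near 0.3 years — small
  against the 0.5-year recovery check. At the 1/450 default prevalence the
  comparison group at this population size carries too few deaths for such
  a check to say anything about correctness.
* **SMR interval coverage**: 200 replicates of 40,000 persons at 0.4%
  prevalence. Rare exposure in large pools keeps matched comparisons nearly
  disjoint across sets (the Byar interval treats expected deaths as fixed,
  so heavy reuse of comparison person-time would inflate its variance), and
  the small expected counts per replicate (~15–20 observed deaths) are the
  regime where the approximation is slightly conservative. The estimator's
  true coverage here is ≈93–95%, not the nominal 95%: the interval ignores
  the sampling noise of the expected-death denominator.
* **Simulated life-expectancy interval coverage**: 200 replicates of
  12,000 persons at 2% prevalence, male comparison group, truth defined as
  the generator's exact central death rates pushed through the same life
  table (discretisation-matched, 80.02 years).
* **Poisson Wald coverage**: 500 replicates of exact Poisson data from a
  known quadratic log-rate.
* **Null study**: 8 cohorts with group hazard ratio exactly 1; YLL point
  estimates scatter around zero. Sparse exposed fits give the YLL a heavy
  left tail (an imprecise quadratic can push modelled old-age rates near
  zero and inflate the exposed life expectancy), so the replicates use 5%
  prevalence where the scatter is ~1.5 years.

## Numerical and design notes

* Dates are integer days everywhere; years = days/365.25 only at
  aggregation and display.
* Medians and IQRs use linear-interpolation quantiles; the convention is
  recorded in the summary metadata. Display percentages round half-up to
  two decimals; machine-readable outputs keep full precision.
* Age-banded rate tables (18–24, 25–34, …, 65+) use exact Poisson
  (Garwood, chi-square quantile) intervals on the death count, per 100,000
  person-years.
* The open-ended life table means a fit implying near-zero rates at the
  cap produces an arbitrarily large e₁₈; this is a faithful property of the
  method on sparse data, surfaced in small demos as implausible exposed
  life expectancies with very wide simulation intervals.
* Known limitations: no overdispersion or spline alternatives to the
  quadratic (by design), no calendar-period dimension in the Lexis
  expansion, no cohort (generation) life expectancy, exposed and comparison
  coefficient draws independent in the CI simulation, and Townsend
  deprivation quintiles pass through descriptively without any derivation
  from census inputs.
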