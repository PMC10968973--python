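# Methods

## Cohort model and exclusions

A cohort is one row per patient with ICD-O-3 topography, age at diagnosis
(years), sex, race/ethnicity (six categories: NH-White, Hispanic,
NH-AIAN, NH-API, NH-Black, NH-Unknown), SEER summary stage
(localized/regional/distant/unknown), diagnosis year (2000–2020),
survival months, vital status, and an autopsy-only flag.  Derived
partitions: age <45 / 45–49 / 50+ (screening-age-motivated cuts) and
diagnosis-year bins 2000–2004 / 2005–2009 / 2010–2014 / 2015–2020 (the
last bin spans six years).

Exclusion rules are applied in a fixed order — unknown stage; topography
outside the nine analyzed subsites (including non-specific C188, C189,
C260 and unscreened sites such as C181 appendix); autopsy-only; missing
survival; zero survival — because a record can violate several rules and
the per-rule counts depend on which rule claims it first.  The order is
part of the contract and the `ExclusionLog` satisfies
`n_in = n_out + Σ counts` by construction.  "Zero days of survival" is
operationalized as `survival_months == 0` regardless of vital status,
matching the month granularity of registry survival recodes.  Histology
filtering (adenocarcinoma NOS, 8140) is a schema-level prefilter: applied
when a histology column is mapped, otherwise the input is assumed
prefiltered.  Topography is accepted dotted or dotless, any case.

## Association analyses

Univariable odds ratios come from the closed-form 2×2 cross-product with
the Wald interval exp(log OR ± z·√(1/a+1/b+1/c+1/d)), z = Φ⁻¹(0.975) ≈
1.959964.  This convention was chosen because it exactly reproduces the
published intervals from the published count columns.  A zero cell is an
error unless the Haldane–Anscombe 0.5 correction is requested.

The multivariable model is main-effects logistic regression of
visualizable-location on the five factors, dummy-coded against references
50+, female, localized, NH-White, 2000–2004.  It is fit by
Newton/IRLS written in-package: start at β = 0, converge on relative
log-likelihood change < 1e-10, at most 50 iterations; rows are first
aggregated into binomial covariate cells so fitting cost is bounded by
the number of distinct covariate patterns rather than patients.
Divergence (any |β| > 30) or a singular information matrix raises an
explicit separation error; a constant outcome is rejected up front.  The
implementation is cross-checked in the tests against statsmodels GLM
coefficients and standard errors — the external library is an oracle,
never the engine.

Report percentages are rounded half-away-from-zero to one decimal;
internal values are never rounded.

## IPW survival analysis

Tumor location is not randomized, so group survival curves are adjusted
by inverse probability weighting with sex and race/ethnicity as
covariates (age and stage are handled by stratification, not weighting).
The propensity model is the same IRLS logistic engine; the default
weights are stabilized (numerator = marginal group share), giving mean
~1 per group and bounded variance without changing the estimand.
Propensities below 1e-6 are counted and warned about, not clipped.  The
weights can be estimated once globally, but the default refits per
stratum, matching the stratified analysis.

The weighted Kaplan–Meier estimator uses weighted event sums d_i and
at-risk sums n_i over distinct event times, Ŝ(t) = Π(1 − d_i/n_i), with
events processed before censorings at tied times; unit weights reduce
exactly to the classical estimator (verified bitwise against lifelines).
RMST(τ) is the exact area of the step function on [0, τ] for τ ∈
{24, 60, 120} months.  A stratum estimate is *not estimable* when the
stratum has fewer than `min_stratum_n` subjects (default 10) or when
follow-up ends before τ with a censored last observation (the curve tail
is then unidentified); when the last observation is an event, the final
step is carried to τ and the estimate is flagged extrapolated.  These
rules mirror the sparse-cell behaviour a registry analysis reports
(e.g. a 45–49/distant cell unassessable at 120 months) without claiming
the registry's exact rule, which is not published.

DRMST is the visualizable-minus-colonoscopy difference within an age ×
stage stratum; DDRMST contrasts the localized-vs-distant gap between
location groups within an age group.  Inference: patients are resampled
with replacement within the stratum; **weights are re-estimated inside
every bootstrap replicate**, so weight-estimation uncertainty propagates;
SE is the across-replicate standard deviation, Z = point/SE with a
two-sided normal p-value, and the reported interval is the percentile CI
at 99% (report parity).  Replicate RNG streams spawn deterministically
from one master seed, so results are bit-reproducible and independent of
evaluation order.  Inference is refused (not silently reported) when more
than 10% of replicates are non-estimable or when the statistic is
constant under resampling (SE below 1e-9 relative — float roundoff).

Multiplicity: Bonferroni within declared families — m = 27 for the DRMST
grid (3 ages × 3 stages × 3 horizons) and m = 18 for the DDRMST family.
Both are configuration values fixed by the analysis plan, not inferred
from how many tests happened to be estimable; the DDRMST family size is
declared because its enumeration is not otherwise derivable from the
grid (3 ages × 3 horizons = 9 double differences; 18 corresponds to two
stage-contrast sets and is kept configurable).

## Synthetic cohort generator

The generator defines the study conditions for every stochastic test.
Defaults emulate the published 309,466-patient cohort's marginal
structure:

- age-group mixture (6.69% / 6.11% / 87.2%) and subsite probabilities
  per age group taken from the subsite-by-age count grid;
- sex (52.1% male) and race/ethnicity mixtures from the cohort
  characteristics table;
- stage mixture per location group from the same table's stage rows;
- location–covariate confounding as additive log-odds on
  logit P(visualizable): defaults ln 1.52 (male), ln 1.56 (NH-API),
  ln 0.76 (NH-Black), etc., matching the adjusted association strengths
  typical of this cohort.  Shifts are centered on the covariate mixture
  so the per-age-group marginal visualizable share stays at the
  configured subsite mixture (to first order; the residual curvature
  error is a fraction of a percentage point);
- survival exponential per (stage, location) cell.  Monthly hazards are
  set by inverting the RMST-at-120-months formula (1 − e^(−λτ))/λ for
  targets 101/99 (localized), 75/66 (regional) and 30/22 (distant)
  months for the visualizable/colonoscopy groups — *mimicry* of the
  qualitative published pattern (localized comparable, distal advantage
  at regional/distant stage, larger localized-distant gap for proximal
  tumors), not a reproduction of registry values, which require
  microdata;
- administrative censoring: uniform entry over the 252-month accrual
  window with follow-up truncated at the window end, so censoring is
  correlated with diagnosis year as in a registry; survival months are
  floored to integers (a floored month of 0 is naturally removed by the
  zero-survival exclusion).

Not emulated: screening behavior, lead-time bias, incidence trends, and
covariate-dependent survival — survival depends only on (stage,
location), so the IPW-adjusted target equals the closed form and
recovery tests have an exact truth.  Passing tests therefore demonstrate
estimator correctness under known confounded-assignment conditions, not
fidelity of any real-data point estimate.

`inject_exclusions` appends rows that each violate exactly one exclusion
rule (exact counts or binomial rates), so the expected exclusion log
equals the injection manifest exactly.

## Validation design and problem sizes

- Printed-count replication: all published univariable ORs/CIs and
  percentages recompute from raw counts to printed precision (exact,
  deterministic, < 1 s).
- Longhand oracles: weighted product-limit and step-integral recomputed
  by explicit loops on ≤ 10-subject fixtures, compared bitwise.
- Closed-form recovery: exponential strata of 4,000 patients, DRMST
  within 3 bootstrap SEs of truth.
- Coverage calibration: 200 outer Monte-Carlo repetitions × 500 inner
  bootstrap replicates on a 600-patient sex-confounded regional stratum;
  the 99% percentile CI must cover the true DRMST in ≥ 96% of outer
  repetitions.  The stratum size (≈300 per location group) was chosen
  once as a realistic scaled-down stratum; the inner replicate count is
  scaled down from the 2,000 used in a full analysis.
- End-to-end: one 10,000-patient cohort with injected OR 2.0 and known
  DRMST, recovered within 3 SEs through the full pipeline.

## Known limitations

- Registry point values for RMST/DRMST and multivariable ORs are not
  desk-reproducible without microdata; they are exercised only
  qualitatively through the generator's mimicry targets.
- The exponential survival model has constant hazards within (stage,
  location) cells; real registry hazards fall with time since diagnosis.
- Percentile bootstrap CIs can undercover slightly in small strata; the
  refusal rules (min stratum size, failed-replicate fraction) bound but
  do not eliminate this.
- Two published percentages (localized 56.6%, 2015–2020 60.0%) do not
  reproduce from their own printed numerator/denominator (which give
  56.5% and 59.5%); the package reports the count-derived values.
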