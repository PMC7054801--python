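# Methods

This note documents the models, rules and numerical conventions
implemented in `claimscreen`, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## 1. Data model

Two delimited-text tables (CSV, UTF-8, ISO-8601 dates) are used
throughout. The *base* table carries one row per beneficiary
(demographics, per-year Part A/B and non-Medicare coverage flags for
2009–2014, vital status); the *claims* table carries one row per dated
code with its coding system (`ICD9_DX`, `ICD9_PROC`, `CPT`, `HCPCS`),
claim source, and optional provider specialty. Real Medicare fixed-width
layouts and specialty code systems are deliberately out of scope: only a
documented free-text `neurology` token is needed downstream. Codes are
stored dotless and uppercase internally ("332.0" ≡ "3320"); readers
normalize on ingest, and normalization is idempotent.

## 2. Case ascertainment

A beneficiary is an incident PD case iff the record contains ≥1 ICD-9
332/332.0 diagnosis code and none of: 331.82 (Lewy body dementia),
333/333.0 (other extrapyramidal disease), or 322/322.0 anywhere without
CPT 62270 anywhere (the "typographic error" pattern — a meningitis code
with no lumbar puncture suggests a mistyped code). Exclusion codes at
*any* date disqualify the case label; the survival stage separately
censors at the *first* excluded-diagnosis date, so both behaviors exist
and are applied where each belongs. When several exclusion patterns
co-occur the reported reason follows the fixed precedence lewy_body >
extrapyramidal > typographic_error. The diagnosis date is the earliest
qualifying PD code; `n_pd_codes` is the raw count of qualifying PD code
events (same-date repeats included); the neurologist flag requires a
qualifying PD code with specialty `neurology`.

## 3. Cohort and sampling conventions

* Eligibility is evaluated against the 2009 base year: age at
  December 31, 2009 in [66 years 11 months, 91 years) — the lower bound
  guarantees two full claim-years of look-back, and the 91st birthday
  disqualifies — plus U.S. residence, Part A/B coverage without
  non-Medicare coverage, alive at January 1, 2010, and no PD diagnosis on
  or before baseline.
* Follow-up runs from 2010-01-01 to the earliest of PD diagnosis, death,
  first excluded-diagnosis date, and 2014-12-31. Date ties break with
  precedence excluded-dx > PD > death; in particular a PD code on the
  death date counts as a PD event (diagnosis precedes death within the
  day). Follow-up years are exact day counts / 365.25 everywhere.
* Incidence is `1e5 × events / person-years`.
* Nested case-control sampling is incidence-density style: every PD event
  is a case with its diagnosis date as reference date; every noncase is
  assigned a reference date drawn with replacement from the empirical
  distribution of case diagnosis dates (uniform over follow-up when there
  are no cases) and is kept as a control only if still alive and
  uncensored on that date. This parallels "controls are noncases who
  survived to a randomly assigned reference date in the same period"; the
  exact law of the control reference dates is a design choice and is the
  main place a re-implementation could legitimately differ.

## 4. Predictors and scoring

Observation windows are half-open `(start, end]`; the unlagged
configuration ends at each person's reference date, the lagged one at
2009-12-31 (so only 2004–2009 codes contribute). Both are reached purely
through the window parameter. Age enters as two linear splines with a
knot at 85, computed at the reference date for case-control scoring and
at baseline for cohort scoring. The seven race/ethnicity categories use
white as reference with "unknown" folded into Pacific Islander/other.
Smoking probability is 1.0 given any tobacco-specific code in the window
(default list: V15.82 and the 305.1x family, configurable) and otherwise
the inverse logit of a configurable logistic smoking model. The
unique-code count is the number of distinct normalized ICD-9 diagnosis
codes in the window.

PD-definition codes (332/3320) are excluded from *all* predictors —
indicators and the unique-code count — because they define the outcome
label; with reference dates equal to diagnosis dates, admitting them
would leak the label into the score. This is an interpretive choice and
is applied consistently in both the pipeline and the generator's ground
truth.

Scoring is `constant + Σ β·x` with exact dot-product semantics; a
coefficient whose feature cannot be resolved is an error, never a silent
zero. The inverse-logit link is applied because the source model is a
logistic regression; every rank-based metric is invariant to it. Model
variants are restrictions of the full term set (`basic`: demographics +
smoking + constipation/RBD/anosmia codes; `basic_plus_codes_count` adds
the unique-code count; `age_only`: the two splines), keeping the full
model's constant — adequate because the variants are compared only
through rank-based and relative quantities. The HCPCS-exclusion switch
zeroes the 54 HCPCS coefficients (their predictor value is assumed 0),
modelling transport to claims systems without HCPCS coding.

The bulk scorer computes code contributions by grouped set arithmetic
over distinct (beneficiary, code) pairs instead of materializing a dense
n×536 indicator matrix; tests verify it equals the per-person feature
extraction + dot product exactly.

## 5. Validation metrics

* AUC is the tie-corrected concordance (Mann–Whitney U / n₁n₀). The CI
  uses the DeLong placement-value variance; the implementation is checked
  against an R pROC oracle frozen into the tests, and against brute-force
  pair counting on thousands of random instances.
* The operating threshold minimizes |sensitivity − specificity| over the
  midpoints of adjacent distinct scores plus sentinels beyond the
  extremes; scores ≥ threshold are positive; ties in balance break toward
  larger sensitivity + specificity, then the smaller threshold.
  Sensitivity/specificity CIs are Wilson intervals (better coverage near
  1 than Wald).
* Crude odds ratios are closed-form (a·d)/(b·c) with Woolf log-scale
  intervals and no continuity correction (a zero cell flags the CI as
  undefined). Mutually adjusted ORs come from a statsmodels Newton/IRLS
  logistic fit (gradient tolerance 1e-8); rank deficiency and separation
  raise explicit diagnostics. The single-covariate logistic OR equals the
  closed-form 2×2 OR, which the tests exploit as a cross-check.

## 6. Survival analysis

Baseline probabilities are cut at their 10%–90% sample quantiles;
label k means value in (edge_{k−1}, edge_k], so ties share the lower
decile; fewer than 10 distinct values is an error. The Cox model uses
nine decile indicators (decile 1 reference), Efron tie handling, time on
study in years, and Wald intervals; deciles without events are flagged
unstable rather than failing the fit. The global test is the
likelihood-ratio test of the nine indicators. The proportional-hazards
diagnostic is the score test of zero slope of scaled Schoenfeld residuals
against ranked event time; with one covariate this is the standard test
(type-I error verified by simulation), with several the reported global p
is the Bonferroni-adjusted minimum across covariates, which is
conservative. Note that the synthetic prodromal mechanism genuinely
violates proportionality for baseline-score deciles — the prodromal
signal identifies imminent diagnoses, so decile effects fade with time —
and the diagnostic correctly reports small p there.

## 7. The synthetic-data generator

What it emulates: the age/sex/race structure of a Medicare 66–90
population (declining age weights, 57.7% female, ~86% white), Gompertz
mortality (rate 0.042/yr at 75, log-slope 0.09/yr, giving a mean
follow-up near 4.4 of 5 years), a latent PD process at 461 per 100,000
person-years modulated by age (log-HR 0.05/yr), a uniform (0, 5]-year
onset-to-diagnosis delay (mean 2.5 years, in the range of the observed
mean time to first code), post-diagnosis PD code repetition (0.5/yr) and
a 15% per-code neurologist probability, tobacco codes in 35% of the 50%
ever smokers, threefold emission of smoking-associated codes among
smokers, and rare exclusion-code carriers (~0.2% each).

The PD hazard is normalized with expected-person-time weights (the
integral of each person's Gompertz survival over the 5-year horizon) so
that the realized event rate is unbiased for the configured incidence
despite age being correlated with both the PD and death hazards.

The signal mechanism: each positively weighted model code's emission rate
is multiplied by `exp(enrichment × β⁺)` between latent onset and
diagnosis (enrichment default 1.75, chosen so full-model discrimination
sits in the realistic "good performance" regime, AUC ≈ 0.83 unlagged).
Coupling the enrichment to the coefficients makes two properties
non-vacuous: all-zero coefficients give chance discrimination, and
scaling all coefficients scales the planted signal, not just the score
weights. Negative-coefficient codes are *not* thinned during the
prodrome; they act as protective noise (a multiplicative thinning scheme
would add machinery with no corresponding test surface). Demographic
terms other than age (sex, race, smoking) carry epidemiologically signed
stand-in weights but are not coupled to the hazard.

Randomness uses per-stage named substreams spawned from the single config
seed (demographics, death, onset, codes, dates, PD codes, misc), which
keeps generation fully vectorized and byte-reproducible; per-beneficiary
stream isolation (editing one person without perturbing others) is not
provided.

Ground truth records each person's latent onset and realized diagnosis
dates, smoking status, and the true baseline linear predictor. The
latter is computed by an independent in-module route (numpy scatter-adds
over distinct integer-coded pairs, a deliberately different algorithm
from the pipeline's merge-based scorer) so the pipeline-vs-oracle AUC
comparison is a genuine dual-route check.

What it does not emulate — and hence what passing tests do *not* show
about real data: comorbidity correlation structure (codes are independent
Poisson streams; real claims are bursty and co-occurring), calibrated
per-code prevalences (weights are Zipf-like order-of-magnitude
placeholders), coding-intensity drift over calendar time, coverage gaps
mid-follow-up, regional/provider effects, and any real association of
sex, race or smoking with PD risk. Absolute AUC/HR levels on synthetic
data are properties of the stand-in configuration, not estimates of
real-world performance.

## 8. Coefficient stand-ins

The shipped `synthetic_full_coefficients.csv` (536 code terms, 54 of them
HCPCS, plus demographics/smoking/unique-count and a constant of −11.5)
and `synthetic_smoking_model.csv` are deterministic constructed
stand-ins with the published model's *shape*: a clinically motivated core
(constipation family, RBD 327.42, smell/taste disturbance 781.1,
movement/gait/fall codes, brain imaging and B-12/TSH work-ups positive;
smoking-related, cardiovascular, cancer and preventive-care codes
negative) padded with small-coefficient filler codes. Real coefficient
files in the same CSV dialect drop in without code changes.

## 9. Problem sizes and numerical choices

Default test and reproduction sizes: the shared large synthetic
population uses n = 100,000 (acceptance properties) and the reproduction
script n = 60,000; module tests use 1,500–20,000. Schoenfeld type-I
calibration uses 200 replicates of n = 200; Cox recovery 5,000 per group;
logistic recovery n = 50,000. Zero-length follow-up is nudged to half a
day before Cox fitting; inverse-logit saturates rather than erring at
extreme linear predictors; coefficient CSVs are parsed with round-trip
float precision; all samplers take explicit integer seeds and the
pipeline derives stage seeds deterministically from the run seed.
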