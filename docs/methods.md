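# Methods

## Study design being emulated

Two complementary views of the same comparative-safety question — do DPP-4
inhibitors carry a higher cardiovascular risk than metformin? — drawn from
two kinds of data source:

- a **spontaneous reporting system**, which contains only reported
  adverse-event cases (no denominator, hence no incidence), analysed by
  disproportionality: is the drug–event pair reported more often than its
  margins predict under independence?
- a **claims database**, which has person-time and therefore supports a
  new-user active-comparator cohort with propensity matching, per-outcome
  hazard ratios, and a prespecified non-inferiority margin.

Neither source can be redistributed, so the package's study conditions are
fixed in two synthetic generators whose ground truth the downstream stages
must recover.

## BCPNN information component

For a 2×2 case-level table the model places conjugate Beta priors on the
joint and marginal reporting probabilities. Priors are the WHO-UMC
pseudo-counts α₁ = β₁ = γ₁₁ = 1 and α = β = 2, with the joint total
γ = γ₁₁(n..+α)(n..+β)/((n₁.+α₁)(n.₁+β₁)) chosen so the prior IC is centred
at independence for the observed margins. `bcpnn.ic_moments` implements the
closed-form posterior mean and variance of IC = log₂ p₁₁/(p₁. p.₁);
`bcpnn.ic_credible_interval` forms E ± z√V with z = 1.959964 (z is a
parameter should a 2.0 convention be preferred); the SDR criterion is the
strict IC025 > 0.

**Approximation regime.** The closed-form E(IC) is the log of the ratio of
posterior means, not the posterior mean of the log. The two differ by the
digamma correction, ≈ −1/(2(n₁₁+γ₁₁) ln2) bits plus analogous (smaller,
opposite-signed) margin terms: ~0.066 bits at n₁₁ = 10, crossing 0.02 bits
only around n₁₁ ≈ 35, and negligible beyond n₁₁ ≈ 100. Likewise the normal
interval understates the left skew of the exact posterior for small joint
cells (~0.15 bits at the 2.5th percentile for n₁₁ = 10). The Monte-Carlo
oracle (`bcpnn.mc_ic_oracle`, direct Beta-posterior sampling) quantifies
both effects; the closed-form *variance* tracks the oracle within ~5%
throughout. Replacing the closed form with the exact digamma moments is
deliberately out of scope: the closed form is the estimator under study.
Consequence: tables with n₁₁ ≳ 35 are in the regime where mean and interval
agree with the exact posterior to ~0.02/0.05 bits; smaller joint cells are
not, and the validation suite reports the measured deviation rather than
hiding the regime.

A vectorized variant (`ic_moments_arrays`) backs the calibration studies;
under exact independence at n.. = 10⁵ with 1% margins the measured SDR rate
is ≈2.2–2.4% against the ≤5% acceptance bound (nominal ≈2.5% one tail).

## Spontaneous-report generator

Each case falls in one cell of the target drug × event cross with joint
probability `reporting_ratio × target_drug_share × target_event_share`
(validated to stay below both margins); marginal shares default to 1%, the
order of a moderately common drug class and event group in a
half-million-case database. Background drugs and events attach
independently (25 each, probability 0.03) and never correlate with the
target pair, so the target table is the only signal carrier; cases that
would otherwise be empty get one forced background label. One report per
case; duplicate-case handling is out of scope. Target mentions are always
suspect-role; background mentions split 50/50 suspect/concomitant so the
suspect-only filter is exercised.

## Claims generator

Per patient: age from a normal (52.2, 9.74²) truncated to [20, 75) — the
claims population this emulates excludes the late-elderly insurance segment
— with 70% male; four standard-normal covariates plus standardized age and
the male indicator form the covariate vector x. Treatment follows
logit P(treated) = 0.66 + xᵀβ_t (≈66–68% treated, the observed two-to-one
prescribing mix); event times per outcome are exponential with hazard
h₀ exp(xᵀβ_o) · HR^treated (Weibull shape exposed for proportional-hazards
stress tests). Nonzero β_t and β_o on shared covariates is the confounding
channel; the default confounded scenario uses β_t = (0.5, 0.4, 0.6, 0.5,
0.4, 0.3) and β_o = (0.5, 0.3, 0.5, 0.4, 0.3, 0.2), which biases the crude
MACE hazard ratio to ≈2 when the true ratio is 1.

Calendar structure: one initiation dispensing per patient uniformly in
2017-04-01..2017-06-30, administrative study end 2020-06-30. Death and
disenrollment are a single censoring process (exponential, 0.004/month) —
claims data rarely distinguish them — giving a mean follow-up of ≈33 months.
Baseline hazards 0.00125 (myocardial infarction), 0.0020 (stroke), 0.0036
(heart failure) per person-month put cumulative risks near 4%, 6.5%, 11%,
the order of the published incidence table. Planted protocol violations
(washout fill at −45 days, primary cardiovascular diagnosis at −30 days,
controlled-drug fill at −180 days) are recorded in a truth table so
exclusion bookkeeping is testable; a planted "violation" fill that lands
inside the enrollment window legitimately becomes the patient's earlier
index instead, and the validation accounts for that.

What the generator does **not** emulate: real MedDRA/ICD-10 vocabularies,
dose and adherence, switching, competing-risk death, non-proportional
hazards (by default), reporting biases such as stimulated reporting.
Passing tests therefore show the estimators are correct *given* the model's
assumptions, not that the assumptions hold in any real database.

## Cohort construction

New user: first study-class dispensing in the window with no study-class
dispensing in the prior 3 months. The source design says "any drug"; on
claims data a literal all-drug washout is rarely intended (it would exclude
anyone on chronic therapy), so the default washout checks the two study
classes only, with `strict_all_drug_washout` available. Same-day initiation
of both classes excludes the patient. Exclusions, applied sequentially with
per-stage attrition counts: qualifying cardiovascular diagnosis in the
prior 3 months, controlled-drug dispensing in the prior 12 months (the real
code list is configuration; the generator uses a sentinel class), age ≥75
at index, no enrollment coverage at index.

All lookbacks are half-open `(index − k months, index)`; a month is
30.4375 days. Outcomes are admission-primary diagnoses matched by ICD-10
prefix (defaults: MI I21–I22, stroke I60–I63, heart failure I50; MACE is
the MI ∪ stroke prefix union, "all cardiovascular" the union of all three —
composites are evaluated at the subject's first qualifying event, so their
counts are bounded by max ≤ composite ≤ sum of components). Follow-up ends
at the first qualifying diagnosis or censoring at min(disenrollment, 75th
birthday, study end). A diagnosis on the index date itself counts as an
event at half a day rather than excluding the subject — the alternative
(dropping same-day events) silently deletes the highest-risk person-time.

## Propensity matching

Scores by maximum-likelihood logistic regression (statsmodels); constant
covariates are dropped with a warning, perfect separation raises an error
naming the offending covariate. Matching is greedy 1:1 nearest neighbor on
the logit score, without replacement, treated subjects visited in
seed-shuffled order, caliper 0.2 × SD of the pooled logit scores, distance
ties to the lower comparator id. Greedy (not optimal) matching is the
conventional reading of "nearest neighbor"; on dense overlapping score
clouds it is measurably 1.5–1.8× the optimal-assignment total distance while
matching the same subjects within the caliper — balance, not total
distance, is the estimand that matters, and the default confounded scenario
lands every post-match |SMD| below 0.04 against the 0.1 convention.

## Survival analysis

The matched-cohort hazard ratio comes from a univariable Cox partial
likelihood on the group indicator, maximized by Newton's method with
Efron's tie correction (Breslow by flag); for one binary covariate the
score and information reduce to sums over distinct event times, which makes
the ~700 fits in the validation suites cheap and reproducible. No
covariate adjustment and no pair-robust variance post-match, matching the
design being emulated. lifelines is the independent cross-check (agreement
to 4 significant figures under heavy ties), and a naive O(n²) grid oracle
confirms the maximizer. An event-free arm makes the likelihood monotone;
this is reported as an error, not a number. Cumulative incidence is
1 − the product-limit estimator per group. Non-inferiority: upper Wald 95%
limit strictly below the margin (1.3).

Measured operating characteristics at the study conditions (seeded, also
recomputed by `scripts/acceptance.py`): CI coverage 94–95% at 2,000/arm
over 500 null replicates; with true HR 1 at 2,474/arm and ≈10–11%
cumulative event risk (hazard 0.0035/month, censoring 0.004/month, ~37
month horizon — a design chosen a priori to give ≈0.85 power by the
standard SE ≈ √(1/E₁+1/E₂) calculation), 85–86% of 200 trials conclude
non-inferiority.

## Problem sizes and numerics

Validation suites run at: 2,000 independence replicates of n = 10⁵;
10⁶ Monte-Carlo draws × 10 tables; 500 coverage replicates × 4,000
subjects; 10 confounded populations × 10,000 patients; 200 non-inferiority
trials × 4,948 subjects — sizes chosen to keep Monte-Carlo error well
inside each acceptance band. Newton iterations stop at |score| < 10⁻⁹ with
steps clipped to ±2; the logistic fit requires gradient norm < 10⁻⁶.
Deterministic outputs everywhere given a seed; child seeds are drawn below
2³¹ from a parent generator.

## Known limitations

- The closed-form IC's small-n₁₁ bias (above) is a property of the
  estimator under study, reported rather than corrected.
- Greedy matching guarantees caliper and without-replacement properties,
  not minimal total distance.
- The non-inferiority track estimates a marginal hazard ratio; with strong
  unmeasured heterogeneity marginal and conditional ratios differ
  (non-collapsibility), which the synthetic checks sidestep by construction.
- Exact-date arithmetic uses the 30.4375-day month; day-level rounding can
  move an event by up to half a day relative to continuous time.
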