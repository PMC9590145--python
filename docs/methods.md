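# Methods

## Model and assumptions

The health process is a discrete-time Markov chain on three states —
non-disabled, disabled, dead — evaluated on a monthly grid. Disability here
is a binary cut of an administrative care-needs scale; recovery is allowed
because certifications can lapse. Four transition probabilities are
parameterised by a multinomial logit per origin state with the retention
outcome as reference and a linear age term:

η_ij(x) = a_ij + b_ij (x − c), with centring age c = 80 years. Centring in
the middle of the observed range keeps intercepts interpretable (monthly
log-odds at 80) and the optimisation well conditioned; reported parameters
are always in this centred form, and the file writers store c alongside
them. Within a fitted group the chain is otherwise homogeneous: no
covariates enter by default, because analyses are run as independent fits
per exposure group and stratum rather than by covariate adjustment. A named
covariate-slope hook exists on `TransitionParameters` for external use but
is off by default.

Key structural assumptions:

- **Month resolution.** All times are integer months since baseline;
  baseline ages are resolved to the month grid. This matches yearly
  administrative transfers with dated events and makes interval likelihoods
  products of monthly matrices.
- **Exact death months.** The likelihood factor for a death observed at
  month d after a last living observation at month w is the probability of
  remaining alive through month d−1 and dying in the final month,
  Σ_k [Π M]_{s,k} M(d−1)_{k,dead} over the living states k. Death dates
  from administrative records are exact, so death is not treated as
  interval-censored; an interval-censored-death option is out of scope.
- **Non-informative emigration.** Emigration right-censors the observation
  sequence; the likelihood simply stops. No informative-dropout model.
- **Linear age on the logit scale.** Higher-order age terms are not
  implemented; extrapolation beyond the observed age range follows the
  logit-linear term. This is a known gap — a strongly non-Gompertz hazard
  would be mis-specified.

## Estimation

`TransitionModel.fit()` maximises the panel likelihood with BFGS on the
*mean* log-likelihood per transition pair (so the gradient tolerance,
default max-norm 1e-5, is independent of sample size), using central
finite-difference gradients; maximum 500 iterations. The covariance is the
inverse of the numerical negative Hessian (statsmodels `approx_hess`) at
the optimum, rescaled to the total-likelihood scale. Default initial
values: intercepts −4 for the two death transitions, −5 for disability and
recovery, slopes 0 — inside the plausible region for monthly probabilities.

Transitions with no observed pair of their type (e.g. no disabled
observation anywhere) are not identifiable; their parameters are excluded
from the optimisation, held at the initial values, flagged in the
convergence block and given NaN standard errors. Convergence status is
reported as-is; `profile_check` perturbs each estimated parameter ±2 SE to
verify the optimum and compares a small-step second difference with the
Hessian diagonal.

Likelihood evaluation is exact, not approximated: monthly step matrices are
built for the whole age grid in one vectorised pass and interval products
are computed per unique (start month, length) key, batched by length. A
transparent per-record implementation (`record_log_likelihood`) computes
the identical sum and serves as the cross-check oracle in the tests
(agreement to 1e-10).

## Life table

From a starting age (default 65, the reporting convention) the occupancy
vector is propagated to `max_age` (default 110) and each living state is
credited a full step for the mass occupying it at the step's start. No
half-step correction is applied by default; the credit convention is
recorded in `method_tags`. TLE = DFLE + DLE is an identity of the
recursion, not a tolerance. Truncation at 110 changes DFLE at 65 by less
than 0.01 years for all default-scenario parameters (checked in the tests);
raising `max_age` is the remedy for low-mortality parameter sets. Reported
expectancies condition on starting non-disabled, matching cohorts that
exclude prevalent disability at baseline; an explicit
`initial_distribution` (e.g. the quasi-stationary prevalence from
`stable_prevalence`) gives the prevalence-weighted variant.

Confidence intervals use parametric simulation (default 2,000 draws from
the asymptotic normal of the estimated parameters, percentile 2.5/97.5),
because expectancies are markedly nonlinear in the parameters; a delta
method would understate the asymmetry. Draws are seed-reproducible and kept
on the result object so group differences (`dfle_difference`) can form
percentile intervals of the difference; draws of independently fitted
groups are independent and flagged as such. A non-PSD covariance is an
error with an explicit opt-in nearest-PSD repair.

Published CI widths for this class of analysis are produced by other
software with an unstated interval method; no attempt is made to match
their widths, only the estimand.

## Synthetic cohorts

`simulate_cohort` draws latent monthly paths from ground-truth parameters
per (group, sex) cell, starting non-disabled, and observes them at annual
waves over 13 years (months 0, 12, …, 156); death months are recorded
exactly, and an independent per-month emigration hazard (default 4e-4,
≈4–5% lost over follow-up) truncates the sequence. Baseline ages are
truncated normal on [65, 95] with group-specific means (76.0 / 73.1 / 71.4
years, SDs 6.2 / 5.3 / 4.9) following the published baseline structure of
the emulated cohort; group proportions 0.447 / 0.243 / 0.310 and a male
share of 45.1% likewise. The generator is byte-reproducible per seed and
can emit latent paths for debugging.

The default scenario's ground-truth transition parameters are the
package's own choice, fixed once for qualitative plausibility: DFLE ordered
≥20 > 10–19 > 0–9 within sex, death proportions decreasing with more teeth,
women with longer TLE and larger DLE than men (disabled mortality ≈29%/yr
for men vs ≈15%/yr for women at 80), and expectancies in realistic ranges
(men TLE ≈17–20 y, women ≈21–24 y at 65, DFLE gap between extreme teeth
groups ≈2–3 y). They are deliberately **not** calibrated to any published
expectancy values — matching those and then "validating" against them would
be circular. Oral-care and lifestyle covariates are sampled with
group-dependent frequencies but have no effect on transitions by default,
which is what makes the null-effect checks of the care-split analysis
meaningful.

What passing tests therefore show: the estimator recovers the generating
process of this design (interval censoring, exact deaths, independent
censoring, logit-linear age) with correct uncertainty. What they do not
show: robustness to informative dropout, state misclassification,
time-varying exposures (covariates are baseline-only, as in the emulated
study), or hazards that are not logit-linear in age.

## Problem sizes and numerical choices

The test suite validates estimation on 50 replicate cohorts of n = 2,000
with annual waves over 13 years — large enough for asymptotic coverage
(checked: each intercept within 3 SE of truth in ≥47/50 replicates, Wald
coverage within binomial tolerance of 95%, DFLE CI coverage ≥42/50) while
keeping a full run in minutes. The acceptance script uses 20 replicates for
the end-to-end coverage figure and a 12,000-person cohort for the group
report; these sizes are reporting choices, and all of them scale up by
changing one constant. Closed-form oracles (fundamental matrix, geometric
lifetime) are checked to 1e-10 with `max_age` extended until truncation is
below that tolerance.

All softmax evaluations are log-sum-exp guarded; probabilities underflow to
exact zero only beyond logits ≈ −745, in which case an observed impossible
transition yields −inf with a per-record diagnostic rather than an
exception. Percentages in accounting tables round half-up to one decimal,
the convention of the printed tables they mirror (one printed cell, 30.2%
for 802/2649, is internally inconsistent with its own counts, which give
30.3%).

## Exclusion cascade and accounting

`apply_exclusions` removes records in the fixed flowchart order — no
consent for records review, prevalent disability at baseline, death/move
before follow-up start, missing exposure — attributing doubly-excludable
records to the first matching criterion, and logs counts per step.
`synthetic_reference.py` provides synthetic stand-in datasets encoding only
the published marginal counts (participant flow; outcome distribution by
sex and teeth group) so these operations can recompute the printed figures;
no record in them corresponds to a real person.

## Known limitations

- Stratified analyses refit the model within each cell; small cells hit the
  minimum-size guard (default 50) and are reported, not estimated.
- The wide-wave CSV dialect encodes wave months in column names
  (`state_m0`, `state_m12`, …); irregular per-participant schedules need
  the tidy-long dialect.
- No continuous-time (intensity-matrix) formulation; the method is the
  discrete embedded chain, and very fast within-month dynamics are
  invisible to it.
- Missing covariates are excluded listwise per analysis with counts
  reported; no imputation.
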