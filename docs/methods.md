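# Methods

## Model and estimation

MixRFb couples a random-forest classifier with a random-intercept logistic
model for clustered binary outcomes:

    logit P(y_ij = 1) = logit f(x_ij) + b_i,    b_i ~ N(0, sigma_b^2),

where rows are patient-days and clusters are patients. Estimation is
single-pass by default: (1) fit the forest to the death indicator on all
rows; (2) clip its out-of-bag probabilities to `[eps, 1 - eps]`
(`eps = 1e-6`, forests emit exact 0/1 votes) and take their logit as a
per-row offset; (3) estimate `{b_i}` and `sigma_b^2` by maximizing the
Laplace-approximate profile likelihood of the random-intercept logistic
model with that offset; (4) iterate step 3 until `|delta sigma_b^2| < tol`
(default 1e-3) or `max_iter` (20). An optional `refit_forest` mode re-grows
the forest each outer iteration with rows down-weighted by
`exp(-(2y - 1) b_i)` — rows the intercept already explains count less; it
is off by default because the single forest fit is simpler and the offset
construction ("first the forest, then the mixed model") is the intended
architecture.

Random-effect estimation details: intercepts are separable across patients
given the offset, so posterior modes are per-patient Newton iterations
(vectorized, step clipped at 4 on the logit scale, tolerance 1e-10, maximum
200 steps; failure raises with the step trace). The variance maximizes the
Laplace objective on the log-variance scale by bounded scalar search over
`sigma_b^2 in [1e-8, 400]`; the degenerate fit `b = 0` is compared
explicitly so boundary solutions report exactly zero. The linear GLMM
baseline alternates a binomial GLM step (current modes as offset) with the
same variance step, with 0.5 damping on coefficient updates; an exploding
first GLM step means separation and is an error, a later explosion means
the near-saturating-offset regime and the last stable coefficients are
kept. On correctly specified data (rows conditionally independent given
the intercept) the fixed effects and variance agree with `lme4::glmer`
(Laplace) to within a tenth of a logit — checked by an R cross-check test.

### Forest bagging unit

The MixRFb forest bootstraps **patients**: each tree is grown on a
with-replacement draw of patients, so all rows of a patient are jointly in-
or out-of-bag and the out-of-bag probability of a row never uses any row of
the same patient. With conventional row bagging, in-bag sibling rows (same
covariates, same outcome) leak the patient's outcome into its "out-of-bag"
prediction; on clustered synthetic data this inflates apparent OOB AUC by
about 0.10. The plain-RF comparator keeps conventional row bagging on
purpose — it is the model that ignores clustering. Patient grouping uses
order-of-first-appearance factorization, which makes fits invariant to
relabeling patient identifiers. Forest defaults: 500 trees,
`mtry = floor(sqrt(p))`, Gini splits, minimum node size 5.

### What sigma_b^2 means here — an honest caveat

In-hospital mortality is one event per admission, so the outcome is
*copied* across a patient's rows. The row-level likelihood treats those
copies as conditionally independent given `b_i`; the only way it can
represent their perfect correlation is to push `sigma_b^2` up until each
patient's probability saturates toward their outcome. Consequently, on
cohorts with patient-constant outcomes the fitted `sigma_b^2` is large
(order 10^2 on the default cohort) **regardless of the generator's true
intercept variance**, and conditional predictions for training patients
saturate toward their observed outcome. This is a property of the model
class, not of the implementation — a logistic-GLMM fit with any standard
mixed-model package maximizes the same likelihood and behaves the same
way. `sigma_b^2` is therefore reported as a measure of residual
within-patient outcome association absorbed by the intercepts, not as an
estimate of a biological variance component; genuine variance recovery
holds (and is tested) on data whose rows are conditionally independent
given the intercept, e.g. repeated events within a patient.

## Synthetic cohort generator

The generator emulates a mid-2010s single-centre ICU cohort: 286 patients,
79/286 deaths, five daily rows each. Patient covariates: age ~
N(69, 12) truncated to [18, 100]; female with probability 94/250; diabetes,
cardiovascular and respiratory flags independent Bernoulli (75, 128,
51 / 250), `any_comorbidity` their logical OR (~0.73 — note independent
flags cannot also match a lower printed any-comorbidity marginal, the OR
consistency invariant wins); SAPS ~ N(40, 14) truncated at 0; RDW a noisy
constant per patient, baseline N(14.5, 2.0) truncated at 10% with daily
s.d. 0.5% — RDW is stable over a five-day stay.

The outcome is one Bernoulli per patient with

    logit p_i = alpha + mean_d[ eta_id ] + b_i,   b_i ~ N(0, sigma_b^2),

`alpha` solved by root-finding so the expected death fraction equals the
target (unsolvable configurations raise). The fixed-effect structure was
calibrated once against the published performance pattern of such cohorts
— weak standalone discrimination of any single variable against a strong
multivariable machine-learning fit, with the age x RDW combination the
dominant signal — and then frozen:

| component | default | rationale |
|---|---|---|
| age | +0.03 /y | near-linear risk increase with age |
| rdw | +0.02 /% | small linear component |
| rdw hinge | +0.4 /% above 16% | risk rises sharply above ~16% |
| age x RDW | +4.0 logits when age >= 65 and RDW > 15 | elderly + anisocytosis exceeds the sum of the parts |
| saps | +0.07 /pt | moderate severity summary (raw AUC ~0.67) |
| female | +0.2 | minor |
| any comorbidity | +0.4 | minor |
| sigma_b | 1.5 | substantial unexplained patient heterogeneity |

Missingness defaults mimic incomplete baseline characteristics: ~12.6% on
the categorical covariates, 10% on RDW, capped at 23% everywhere;
mechanisms are MCAR or MAR-on-outcome (death rows masked at a configurable
multiple of survivor rows, total rate preserved). What the generator does
**not** emulate: correlated comorbidity flags, informative (non-random)
missingness patterns tied to clinical workflow, measurement drift between
laboratories, other longitudinal labs, or competing discharge/censoring —
so green tests show the pipeline's statistical machinery works under
controlled clustering and missingness, not that the model transfers to any
particular real ICU.

## Imputation

Chained equations, fitted on training data only: missing cells initialized
from observed marginals, then 5 cyclic sweeps; continuous columns use
linear regression with predictive mean matching (5 donors), binary columns
logistic regression with a Bernoulli draw (a weak ridge, C = 1e4, keeps
separated sweeps finite; a single-valued observed column falls back to its
marginal rate). The final sweep's models, donor pools and marginal pools
are frozen; test cohorts are completed in one pass from those frozen
objects, so nothing on the test side can alter the training side. One
completed dataset per call — the validation workflow trains one model per
replication, so multiply-imputed stacks with pooling are deliberately not
implemented. The outcome is excluded from the imputation predictors so the
same frozen models can complete rows whose outcome is unknown at
prediction time.

## Bootstrap validation

"Bootstrap resampling into 60/40" is internally tense (the OOB complement
of a full bootstrap is ~36.8%): resolved by drawing `ceil(0.6 n)` patients
with replacement and testing on the never-drawn remainder, which honours
both the bootstrap and the 60% wording; the realized test fraction is
whatever the complement yields (~48% of patients on average at n = 286). A
plain 60/40 split is available as `split_mode="mc"`. Resampling is by
patient; duplicated draws and oversampled minority patients get fresh
aliases that keep their source's random-effect group. Metrics are
row-level (each patient-day scored, the patient outcome repeated), F1 at
threshold 0.5 on the death probability; a patient-level AUC on mean daily
scores is reported alongside. Replications whose test set has a single
outcome class are skipped and counted. Every replication's seed derives
from the master seed, so reports are exactly reproducible.

## Importance suite

Permutation importance is the mean decrease in *accuracy* (threshold 0.5,
population predictions) over `n_repeats` column shuffles. The multi-way
report adds: summed Gini impurity decrease per variable; root-split counts
with a one-sided exact binomial tail `P(Bin(n, p0) >= k)` where
`p0 = 1/p` by default (split variable uniform over all p covariates) with
`mtry/p` available, and `n` reported under both conventions (trees /
all internal nodes, root counts being the default plot); mean minimal
depth (root = 0; trees without the variable contribute the forest's mean
tree depth + 1 and are flagged); and pairwise conditional minimal depth
(shallowest child-variable split strictly inside the maximal
parent-rooted subtree, relative depth). Partial dependence sweeps the
2.5–97.5 percentile range of the variable (no extrapolation into the
tails) and averages population predictions over the observed background.

## Univariable layer

Binary predictors: cross-product odds ratio on the 2x2 table with Wald CI
`exp(ln OR ± 1.96 sqrt(1/a + 1/b + 1/c + 1/d))` and z-test — identical to
the univariable logistic MLE; zero cells raise unless the 0.5 continuity
correction is requested. Continuous predictors: per-unit OR from a
logistic fit. Rows collapse to one per patient (first observed day) before
fitting, because a baseline table describes patients, not patient-days.
Descriptive ROC uses the raw variable as the score (first-day or
patient-mean value).

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale by choice: bootstrap
ordering uses B = 100 replications with 100-tree forests on the default
286-patient cohort; variance-component checks use 10 seeds of 500-patient
cohorts with 300-tree forests; metric oracles use 1000 random instances;
Monte-Carlo binomial checks use 1e5 draws with 3-standard-error bands.
Numerical guards: probability clip 1e-6 before any logit; variance search
bounded in [1e-8, 400] on the log scale; Newton steps clipped at 4 logits;
GLM coefficients beyond 30 logits treated as separation.

## Known limitations

* `sigma_b^2` saturates on patient-constant outcomes (see above); it is
  not comparable across datasets with different rows-per-patient.
* Model A and the plain forest differ only in bagging unit when scored on
  unseen patients (population mode), so their validated AUCs are close;
  the mixed-effects machinery pays off in conditional prediction and in
  honest out-of-bag estimation, not in population-mode ranking.
* Random slopes, non-logit links, time-to-event outcomes and multiply
  imputed pooling are out of scope.
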