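# Methods

This note documents the statistical models, the numerical choices and the
limits of what the package's tests demonstrate.

## Risk models and triage

The triage engine evaluates multinomial logistic models with FPUL as the
reference outcome: linear predictors `eta_IUP` and `eta_EP` over a
configurable basis of transformed predictors (log initial hCG, log hCG
ratio, squared log ratio, log progesterone), softmax-normalised into a
probability triple. The basis-term language and the coefficient vectors
live in a YAML config so that a transcription error in the coefficients is
fixable without touching code; a config is rejected unless it declares hCG
in IU/l and progesterone in nmol/l (no automatic unit conversion).

The shipped coefficient file is a **synthetic stand-in**, not the
published models: no public transcription of the original coefficient sets
was available, so the three model structures (M6P with progesterone, M6NP
and M4 without; M4 additionally lacking the squared-log-ratio term) were
fitted by multinomial logistic regression to a 200 000-record draw from
this package's cohort generator. This preserves the models' functional
form and qualitative ordering (M6P discriminates best; M4, without the
quadratic ratio term, cannot express "ratio near 1 is EP-like" and does
worst) but not the published numerical risk estimates.

Boundary conventions, fixed once: Step 1 of the two-step strategy
discharges at progesterone <= 2 nmol/l (inclusive) and assigns the fixed
triple (0.961, 0.022, 0.017) without evaluating the model; the EP
high-risk call is p_EP >= threshold (inclusive, default 5%); the
hCG-ratio band [0.87, 1.66] is inclusive at both endpoints, forced by the
strict inequalities of the FPUL (< 0.87) and IUP (> 1.66) rules. When
progesterone is missing or unreliable (supplements), the two-step strategy
is inapplicable at record level and callers fall back to M6NP; in the
imputation pipeline, progesterone has been imputed by then, so M6P applies
to every completed record and the provenance column records which rule
decided each case. Extreme hCG ratios are not truncated or winsorised
before model evaluation.

## Discrimination

`auc_binary` is the Mann–Whitney concordance (ties count 1/2), delegated
to scikit-learn's ROC implementation and checked in the tests against
exhaustive pair counting. The FPUL-vs-IUP AUC restricts to those two
outcomes and ranks by the conditional risk p_FPUL / (p_FPUL + p_IUP). The
polytomous discrimination index scores each (FPUL, IUP, EP) record triplet
by whether each category's record carries the strictly highest estimated
risk of its own category, splitting ties at the maximum equally (1/r for r
tied records), so an all-equal prediction set lands exactly at the chance
level of 1/3. The implementation aggregates with sorted `searchsorted`
counts in O(n log n) per category; the O(n^3) enumeration is retained only
as a test oracle. Per-centre AUC standard errors use DeLong's
placement-value estimator, validated against a 2 000-resample bootstrap.

## Calibration

Calibration of the estimated EP risk uses logistic regression of the
events on logit(risk) with centre-level random effects:

* the **slope** comes from the joint intercept+slope model with
  independent random intercept and random slope by centre;
* the **intercept** is calibration-in-the-large: slope fixed at 1 (the
  logit enters as an offset) with a random intercept by centre.

Independent (uncorrelated) random effects were chosen as the simpler of
the two standard specifications. The marginal likelihood is maximised
numerically with **adaptive Gauss–Hermite quadrature** (13 nodes per
dimension, nodes recentred and rescaled at each centre's Laplace mode —
non-adaptive quadrature is badly biased once centres hold hundreds of
records, because the integrand is far narrower than the prior spread).
No frequentist mixed-logistic fitter exists in the scientific Python
stack, so this fitter is part of the package; its fixed effects agree
with lme4's `glmer` (adaptive quadrature) to ~1e-4 on test fixtures.
Wald CIs come from a finite-difference Hessian. Fallbacks, recorded as
flags on the result: a single centre collapses to ordinary logistic
recalibration; non-convergence drops the random slope; separation
switches to a ridge-penalised fit. Risks of exactly 0 or 1 are clipped
to [1e-6, 1 - 1e-6] before the logit.

Smooth calibration curves are logistic regressions on a restricted cubic
spline of logit(risk) (5 knots at the 5th–95th percentile quantiles,
degrading to fewer knots when the risk distribution has too few distinct
values); constant-risk inputs yield a flagged single-point curve, and
grid points outside the observed risk range are flagged as extrapolated.

## Clinical utility

Net Benefit at threshold t is TP/n − (FP/n)·t/(1−t). Decision curves
reclassify every record from its estimated EP risk at each threshold in a
grid from 3% to 10% in 0.5% steps (the strategy's fixed 5% label is not
reused), and always include the treat-all and treat-none defaults; a
model is flagged harmful wherever its NB falls below the better default.
Under the two-step strategy, Step-1 cases carry p_EP = 0.017 and are
therefore low risk at every threshold in the grid, which keeps the curve
well defined. Centre-level NB standard errors for pooling come from a
seeded within-centre bootstrap (2 000 resamples by default, configurable
down for desk-scale runs).

## Meta-analysis

Centre-specific estimates are pooled with a normal-normal random-effects
model. Between-centre variance tau^2 is estimated by REML (scalar
restricted-likelihood optimisation), with DerSimonian–Laird as the
non-iterative fallback; the method actually used is recorded on the
result. The 95% prediction interval for a new centre uses the t-based
formula with k − 2 degrees of freedom and is undefined (flagged) below
three centres; a single centre passes through. AUCs, PDI and proportions
are pooled on the logit scale (delta-method SEs; boundary proportions
continuity-adjusted and clipped at 1e-6 before the transform), while
calibration parameters and Net Benefit pool on the identity scale — the
pooling scales are declared choices, as is the decision to exclude a
centre from a specific metric (never globally) when that metric is
undefined there.

## Missing data

Protocol rules run before imputation: a second hCG sample not taken
exactly 2 calendar days after the first is set missing (the 1–3-day
window is the sensitivity variant) and progesterone measured under
supplements is set missing; originals are kept in audit columns.
Remaining gaps are assumed missing at random and filled by chained
equations: log progesterone and the log hCG ratio by predictive mean
matching (Bayesian draws of the regression parameters, 5 donors), the
three-category outcome of women lost to follow-up by a multinomial
logistic draw from fitted class probabilities (parameter uncertainty in
that step is approximated by the fitted probabilities — noted in the
method log). Predictors: log initial hCG, age, bleeding category, centre
as a fixed effect (small centres make by-centre imputation unstable), and
the other imputed variables. Each of the m completed datasets is an
independent chain with 20 burn-in sweeps by default (m defaults to 100;
desk-scale tests use m = 5 with shorter burn-in). Analyses run per
completed dataset and combine by Rubin's rules with the standard MI
degrees of freedom.

## Pipeline order and determinism

The fixed order is: eligibility filter (initial hCG must exceed 25 IU/l,
the level at which urine tests turn negative) → missingness rules →
multiple imputation with lost-to-follow-up women included → per-imputation
strategy evaluation and per-centre metrics → Rubin pooling within centre →
random-effects meta-analysis across centres. Pooling metrics (rather than
predictions) across imputations before meta-analysis keeps the
centre-level standard errors coherent. Every random element (imputation
chains, bootstrap resamples) derives from the single analysis seed, so a
(cohort, config, seed) triple reproduces the report bundle byte for byte.

## Synthetic cohorts

The generator draws the outcome per record from the configured prevalence
triple — default (1338, 930, 334)/2602 ≈ 51.4/35.7/12.8% — with
deterministic centre-specific tilts on the EP log-odds; biomarkers are
outcome-conditional lognormals (configurable correlation between log hCG
and log progesterone) moment-matched so the default cohort has median
initial hCG ≈ 520 IU/l, median ratio ≈ 0.9, median progesterone ≈ 11
nmol/l and ~16% of women at or below the 2 nmol/l cut-off. Missingness
reflects the triage protocol: most women below the progesterone cut-off
never return for a second sample (compliance 0.25), others drop out at a
MAR rate tilted by initial hCG and bleeding; together with a 2-day-target
interval distribution this yields ~29% effective second-hCG missingness,
~8% missing progesterone and ~10% loss to follow-up, the latter tilted
toward falling hCG ratios. `generate_from_model` draws outcomes from a
coefficient set's own risks, giving cohorts on which that model is
perfectly calibrated by construction — the oracle for the self-consistency
tests.

What the generator does **not** emulate: assay-specific measurement error
and detection floors, longitudinal hCG trajectories beyond two samples,
ultrasound findings, non-lognormal biomarker tails, and informative
(MNAR) missingness. Passing tests therefore demonstrate that the
machinery is correct on data with the assumed structure, not that any
strategy achieves a particular performance on real cohorts — the real
coefficient sets and real data are both outside this package.

## Problem sizes used by the test-suite

Self-consistency calibration checks run at n = 20 000 (slope within
±0.05 of 1); parameter-recovery sweeps use 200 cohorts of n = 5 000
through the single-centre path; imputation checks use m = 5; fidelity
checks of the generator use n = 10 000 (and n = 50 000 for rate
convergence). These sizes were chosen to keep Monte-Carlo error well
inside the stated tolerances.
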