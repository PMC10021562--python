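# Methods notes

## The random-utility model

A respondent *i* facing choice set *c* picks the alternative *j* maximising
`U_ijc = X_ijc'β + ε_ijc`. The errors are IID type-I extreme value (Gumbel) —
the distributional assumption under which the choice probabilities take the
multinomial-logit form `P_ijc = exp(X_ijc'β)/Σ_J exp(X_iJc'β)`. The logit is
translation-invariant (only utility differences matter) and exhibits IIA: the
probability ratio of two alternatives ignores every other alternative.

The mixed multinomial logit relaxes both homogeneity and IIA by giving each
respondent their own coefficient vector `β_r = b + s ⊙ z_r`, `z_r` standard
normal, shared across that respondent's eight tasks (panel mixing — the
repeated-task structure makes observation-level mixing incoherent here). The
likelihood integral is simulated: per respondent, the product of task-level
logit probabilities is averaged over draws, accumulated in log space with
logsumexp for stability. Both the simulated log-likelihood and its gradient
(posterior-weighted scores over draws) are analytic.

## Coding and identification

Effects coding uses the **last-listed level of each attribute as reference**
(−1 on all contrast columns). This is a fixed convention recoverable from the
instrument config; level utilities within an attribute sum to zero, so the
reference level's utility is minus the sum of the estimated contrasts. The
opt-out alternative carries all-zero attribute columns plus a constant equal
to one; its coefficient is the utility of not engaging relative to the
average profile.

Money enters either effects-coded (the headline model: preferences over the
four amounts are left free and turn out non-linear) or as one continuous
column for willingness-to-accept work. The continuous column is internally
rescaled to thousands of GMD for optimiser conditioning; the scale is carried
in metadata and WTA is always reported per GMD.

## Design efficiency

The local D-error of a design at point priors is `det(I(β))^(−1/K)` where
`I(β) = Σ_tasks X_t'(diag(P_t) − P_t P_t')X_t` is the MNL Fisher information
of the coded design and K the number of parameters. A singular information
matrix (unidentified design) is reported as an infinite D-error, not an
exception, so the search can simply avoid such designs.

The search is coordinate exchange: start from a random design, visit every
(task, alternative) slot, swap in the candidate profile that most reduces the
D-error, accept only strict decreases (hence a monotone non-increasing
trajectory), repeat to a fixed point, and keep the best of a few random
restarts. Point priors (not a Bayesian prior distribution) are used, matching
a pilot-then-refine workflow in which pilot estimates seed the final design.
Where an orthogonal pilot array of the exact size does not exist, a seeded
balanced random design stands in and is flagged as such in its metadata.

## Estimation details

* MNL: damped Newton from a zero start; convergence at gradient max-norm
  below 1e−6 or relative log-likelihood change below 1e−9. The likelihood is
  concave, so full Newton steps are almost always accepted. Standard errors
  come from the inverse observed information; a respondent-clustered sandwich
  is available by flag. Collinear design columns are reported by name before
  fitting. Coefficients beyond ±10 on the coded-utility scale are flagged as
  suspected separation (the likelihood flattens numerically there, which can
  otherwise satisfy the gradient rule spuriously).
* MMNL: L-BFGS on the simulated log-likelihood, started from the MNL fit with
  SDs at 0.1. Halton draws use successive prime bases assigned to parameters
  in column order, first 10 points dropped, no scrambling (the draw set is
  fully determined by `n_draws`, making every fit reproducible); the long
  sequence is partitioned across respondents. SDs are estimated unconstrained
  and reported as absolute values — the mixing distribution depends only on
  |s|. Observed-information standard errors are obtained by differentiating
  the analytic gradient numerically, and can be skipped in replication loops.
* Logistic regressions: IRLS to gradient max-norm below 1e−8. Separation is
  screened first: a binary covariate with a constant outcome within one level,
  or a continuous covariate splitting the outcome perfectly at a threshold,
  makes the MLE non-finite; such covariates are omitted and recorded with a
  machine-readable reason. Wald intervals and McFadden pseudo-R² (stated
  explicitly in output, since "R-squared" alone is ambiguous for logit
  models) complete the table.

## Willingness to accept

`WTA = −Δβ / β_money` with the money coefficient per GMD as denominator; a
disliked change (Δβ < 0) under β_money > 0 costs positive compensation. WTA
is only defined for continuous-money models — requesting it from an
effects-coded-money fit is an explicit error rather than a silently wrong
ratio. Contrasts between two named levels are built through the coded
columns, which makes them invariant to the reference-level convention.
Intervals are Krinsky–Robb (default 10,000 multivariate-normal draws of the
coefficient vector, 95% percentile interval, seeded); draws with a money
coefficient inside a numeric floor are excluded and the estimate flagged
unstable if the floor binds at the point estimate. The "relationship in
general" contrast is taken as neither → engage (−β_optout in the numerator)
so that the reported figure is the compensation required to enter a
partnership at reference attribute settings.

## The synthetic generator

The generator is the package's evidence base, so its defaults are the study
conditions, fixed once:

* **Choice truth.** The default generating coefficient vector uses the
  published point estimates for the levels that were reported (condom always
  0.679 / never −0.710, immediate payment 0.132, Europe invitation 0.255,
  3–4 nights −0.379, age 30–40 0.212 / 50–60 −0.200, opt-out 0.522).
  Unreported levels are completed by the zero-sum constraint where that pins
  them down (condom half 0.031, age 40–50 −0.012) and otherwise by stated
  conventions: money-level utilities monotone increasing in the amount
  (−0.45, −0.10, 0.15, 0.40), a one-night relationship the most preferred
  length (0.424, with the return visit at −0.300 closing the attribute's sum),
  and payment at trip's end neutral (0.0). All of this lives in
  `configs/study_defaults.yaml`, not in code.
* **Scale.** 242 respondents × 8 tasks × (2 profiles + opt-out), matching the
  study; choices from Gumbel inverse-CDF draws of a seeded generator, one
  coefficient draw per respondent in heterogeneous mode.
* **Survey marginals.** Age normal(39.2, 9.58) clipped to [18, 75];
  occupation categorical with the observed shares (40% registered);
  difficulty paying a GMD 350 bill 85%; months in industry gamma with mean
  110, SD 97; months/year normal(7.4, 2.67) clipped to [0, 12]; WHO-5 total
  normal(16.2, 4.2) rounded and split deterministically across the five
  items; household hunger 12% moderate + 3% high; HIV knowledge as a mixture
  (25% score 9, 47% below 6, remainder 6–8); ever-used-drugs 53.7% (so the
  drug model's ever-user subset is about 130 of 242). Risk outcomes are
  Bernoulli with logits from per-outcome coefficient vectors applied to
  centred covariates; intercepts therefore set the approximate prevalences
  (50% ever tourist sex, 39% condom at last sex, 9% STI, 17% alcohol, ~88%
  recent drug use among ever-users).
* **What it does not emulate.** Covariates are drawn independently — the
  sample's joint distribution, nonresponse, and measurement error are out of
  scope. Passing recovery tests therefore shows the estimators are correct
  for the assumed model at the study's size, not that the original data met
  those assumptions.

## Problem sizes in tests and the acceptance script

The MNL recovery experiment uses 50 replicates at the full 242-respondent
scale (it is cheap). Mixed-logit recovery is replicated 10 times at 242
respondents with 200 Halton draws, and other mixed-logit checks use 80–120
respondents with 50–100 draws — at these sizes the simulated-likelihood
machinery is exercised end-to-end while each fit stays in seconds. The
Krinsky–Robb coverage simulation runs 200 replicates of a reduced 60
respondent × 6 task instrument with a continuous money attribute. Mean
recovery is asserted within 2 Monte-Carlo standard errors for the exact MNL
likelihood and within 3 for simulated-likelihood fits, whose draws add
simulation noise on top of sampling noise.

## Known limitations

* Local (point-prior) D-efficiency only; no Bayesian designs, blocking, or
  interaction designs.
* No latent-class, nested, correlated-coefficient or WTP-space models.
* Small-sample maximum simulated likelihood shows visible upward bias in
  mean coefficients below ~150 respondents; use the MNL for small samples or
  raise the draw count.
* The separation screen is marginal (one covariate at a time); separating
  linear combinations of covariates would only surface as non-convergence,
  which is flagged but not auto-repaired.
* Listwise deletion is the only missing-data strategy, mirroring the
  regression tables the package reproduces.
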