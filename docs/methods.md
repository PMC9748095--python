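# Methods

## The model

The outcome of interest is a zero-inflated count: the number of drinks a
college student reports for a typical week. A substantial fraction of
respondents report exactly zero, and those zeros mix two populations —
students who do not drink at all (structural zeros) and drinkers who
happened to report none that week. The zero-inflated Poisson (ZIP) mixture
captures this:

    Y_i = 0                 with probability pi_i
    Y_i ~ Poisson(mu_i)     with probability 1 - pi_i

    logit(pi_i) = z_i' gamma            (structural-zero submodel)
    log(mu_i)   = x_i' beta_ZIP         (conventional ZIP count submodel)

Exponentiated ZIP count coefficients describe only the latent drinker
class, which is rarely the quantity a trialist wants. The marginalized ZIP
(MZIP) instead places the log link on the overall mean of the whole
population,

    nu_i = E(Y_i) = (1 - pi_i) * mu_i,      log(nu_i) = x_i' beta,

so `exp(beta_j)` is a population rate ratio (RR) and `exp(gamma_j)` is an
odds ratio (OR) for being a structural zero. Internally the Poisson
component mean is recovered as

    log(mu_i) = x_i' beta + softplus(z_i' gamma),

since `1 / (1 - pi) = 1 + exp(z' gamma)`. The likelihood is the ordinary
ZIP mixture evaluated at that induced `mu`; for `y = 0` the contribution
`log(pi + (1 - pi) e^{-mu})` is computed as
`logaddexp(eta, -mu) - softplus(eta)` with `eta = z' gamma`, which is exact
and stable for extreme `eta`.

### ZIP vs MZIP are *not* interchangeable on arbitrary designs

A point worth documenting because it is commonly glossed over: the MZIP
induces `log mu = x'beta + softplus(z'gamma)`, which lies outside the
conventional ZIP family `{log mu = x'beta_ZIP}` unless the softplus term is
expressible in the column span of X. That holds when the design is
saturated over the distinct covariate patterns — intercept-only models, or
a full factorial in binary covariates (e.g. intercept, moderator, arm,
moderator×arm) — where the two coefficient scales are bijective transforms
of the same family, so the maximized log-likelihoods and the shared zero
submodel coincide (we observe agreement at ~1e-14). With a continuous
covariate in the design the two model classes genuinely differ and their
maximized log-likelihoods need not match. The parameterization-equivalence
oracle in the test suite therefore runs on saturated designs, where the
identity is a theorem rather than an approximation.

## Estimation

* **Optimizer.** Quasi-Newton: L-BFGS-B with the analytic gradient,
  followed by a short BFGS polish (`gtol 1e-8`). The likelihood is
  optimized in column-scaled coordinates (each design column divided by
  its max-abs) because the raw baseline-drinks column elongates the
  surface and slows convergence about five-fold; coefficients are
  transformed back exactly.
* **Starting values.** `beta` from a Poisson GLM of the outcome on X
  (whose target, the overall mean, is exactly what MZIP's beta models);
  `gamma` from a logistic GLM of the zero indicator on Z. Both fall back
  to closed-form intercept-only values if the GLM fails.
* **Standard errors.** Observed information by central finite differences
  of the analytic gradient at the optimum (step `1e-5 * max(1, |theta|)`),
  symmetrized and inverted; a singular information matrix falls back to the
  pseudo-inverse with a warning. Wald intervals use the normal quantile
  1.959964 (no small-sample t correction), per standard ML practice.
* **Convergence.** Flagged only when the optimizer reports success (or the
  gradient check passes) *and* the scaled-gradient max is below
  `1e-4 * max(1, |loglik|)`. A failed fit is returned with
  `converged=False` and diagnostics, never silently.
* **Perfect separation.** If any zero-submodel coefficient exceeds 10 in
  absolute value the fit warns and refits with a tiny ridge (`1e-6`) on
  gamma. An outcome vector with no zeros at all triggers a
  weak-identification warning up front.
* **Non-integer outcomes** are accepted (imputation pipelines produce
  them): `logGamma(y+1)` replaces the factorial and only exact zeros are
  treated as zeros; fractional values below 0.5 are *not* rounded.

## The moderation pipeline

Per follow-up wave (4 and 15 months):

1. **Exclusion.** Rows with a missing moderator (high-school drinking
   history) are dropped listwise and counted; at the default generator
   settings this removes about 2% of rows, matching the motivating trial.
2. **Full model.** MZIP with intercept, male, White, first-year, baseline
   drinks, moderator, arm, and moderator×arm, the same set in both
   submodels (mirroring how such trials report both coefficient blocks).
3. **Trimming.** If the overall-mean-submodel interaction Wald p-value is
   >= 0.05, the interaction is removed from *both* submodels and the model
   refit. The tie `p == alpha` trims. The overall-mean submodel decides
   because the intervention effect on the overall mean is the analysis's
   primary target; the zero-submodel interaction is carried but not tested
   for this decision.
4. **Conditional RRs.** `RR(BMI vs PFI | moderator=0) = e^{beta_arm}` and
   `RR(| moderator=1) = e^{beta_arm + beta_int}`; report prose renders a
   ratio r as `100*(r-1)`% higher when r > 1 and `100*(1-r)`% lower when
   r < 1, rounded to whole percents in text (tables keep two decimals).
5. **g-computation.** For each of the four (moderator × arm) cells, those
   two columns are counterfactually fixed for every participant, all other
   covariates stay at observed values, and predicted overall means `nu_i`
   are averaged. Under the log link the ratio of two cells within a
   stratum collapses *exactly* to the coefficient product — used as an
   internal consistency check at machine precision.
6. **Bootstrap.** Nonparametric case resampling (rows with replacement,
   resample size = n, default B = 1000, percentile 2.5/97.5 bounds). The
   trimming decision is frozen at the original-sample decision — resamples
   refit the final model only; whether to re-trim per resample is
   genuinely ambiguous in practice, and freezing keeps the interval
   estimand fixed. Non-converged resamples are dropped and counted; more
   than 5% dropped aborts. An override flag lets the g-computation use the
   full interaction model even when the pipeline trims.

## The synthetic-study generator

The generator emulates a two-arm randomized brief-alcohol-intervention
trial in mandated college students:

* n = 348 with Bernoulli(180/348) assignment to BMI (so ~50/50);
* covariate prevalences 60.1% male, 73.3% White, 61.5% first-year, 80%
  high-school drinking, drawn independently — the emulated study reports
  only margins, so independence is the simplest structure consistent with
  them;
* baseline drinks from an intercept-only MZIP calibrated to the trial's
  descriptive moments (overall mean 7.3, ~5% zeros; structural-zero
  probability 0.0495) — the source reports only moments, so the generator
  stays in the same model family as the analysis;
* follow-up outcomes from the wave-specific MZIP models whose default
  coefficients are the trial's published rate/odds-ratio estimates (4-month
  model includes the moderator×arm interaction, RR 0.61; the 15-month model
  has none), generated conditionally independent given covariates because
  the analysis fits the waves separately;
* 2% MCAR missingness in the moderator only.

Under these defaults the simulated 4-month outcome shows a zero fraction
of ~20% and mean ~5 drinks/week, inside the band the emulated trial
reports. Counts are generated as integers even though the fitter accepts
fractional outcomes.

What the generator does **not** emulate: outcome-dependent attrition at
follow-up (the trial retained 91.7% / 63.2%), arm-specific baseline
differences (the trial shows baseline zero fractions of 2.8% vs 8.3%
despite randomization — a finite-sample artifact the generator does not
reproduce), covariate correlations, and recall error in the moderator.
Passing tests therefore demonstrate correctness of the estimator and
pipeline under the stated data-generating process, not robustness to
informative missingness or misclassification.

## Simulation sizes and numerical choices

* Parameter recovery runs 200 replicates at n = 1000: large enough that
  the Monte-Carlo standard error of a mean-submodel coefficient bias is
  ~0.005–0.01 (so a 0.02 bias bound is meaningful) while one replicate
  fits in well under a second.
* Coverage is reported per coefficient; the calibration band checked for
  the intervention coefficient is [0.92, 0.975], the ~2.5 SE binomial band
  around 0.95 at 200 replicates.
* The interaction type-I error check uses a 99% binomial band around 0.05.
* Bootstrap refits skip the observed-information step (point estimates
  only) and warm-start from the original-sample optimum.
* Simulation guards: a row whose Poisson-component log-mean exceeds 30
  (pi numerically 1) raises an error naming the row rather than returning
  a meaningless draw.
* Seeds propagate through `numpy.random.SeedSequence.spawn`, so every
  table, fit, bootstrap, and recovery study is bit-for-bit reproducible
  from a single integer.

## Known limitations

* Variances are model-based (observed information); no robust/sandwich or
  GEE variant is provided, and negative-binomial or marginalized ZINB
  extensions are out of scope.
* The trimming rule is a significance-based model selection step; its
  post-selection effect on downstream intervals is inherited, not
  corrected, exactly as in the emulated analysis.
* The bootstrap treats the trimming decision as fixed (see above).
* With very small samples or very high zero-inflation the zero submodel
  can separate; the ridge fallback stabilizes the fit but slightly biases
  gamma toward zero (penalty 1e-6, negligible at the sizes used here).
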