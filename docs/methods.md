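# Methods

`bpjoint` implements a Bayesian multivariate joint model linking two
longitudinal blood-pressure outcomes to the time to chronic kidney disease
(CKD) in a hypertensive cohort, together with the descriptive survival
layer, the longitudinal mixed submodels, the closed-form sample-size
calculators, and a synthetic-cohort generator that draws from exactly the
joint law the model assumes.

## Model

For subject i and outcome k (k = 1 SBP, k = 2 DBP, both on an internal
scale of mmHg/10):

    y_ki(t) = eta_ki(t) + eps_ki(t),      eps ~ N(0, sigma_k^2)
    eta_ki(t) = x_ki(t)' beta_k + z_ki(t)' b_ki
    b_i = (b_1i, b_2i) ~ N(0, D)

with x(t) = [1, B(t), w_long] and z(t) = [1, B(t)], where B is a natural
cubic spline in months since diagnosis and w_long are baseline covariate
dummies (sex, diabetes, coronary heart disease, acute kidney injury,
hypertension stage, drug regimen, hypertension duration).

The hazard of CKD is

    h_i(t) = h0(t) exp[ gamma' w_i + sum_k sum_l alpha_kl f_kl(t) ]

where h0 is piecewise-constant over intervals whose cutpoints sit at
event-time quantiles, w_i are baseline covariates, and the f_kl are
functionals of the latent (error-free) trajectory selected by the
association structure:

* `current_value`: f = eta_k(t) − c_k
* `slope`: f = 3 · d eta_k/dt  (the quarterly rate of change; visits are
  quarterly, so reported slope coefficients are per 3-month change)
* `value_and_slope`: both
* `area`: f = ∫_0^t (eta_k(s) − c_k) ds
* `area_and_value`, and `none` (no shared dependence)

`c_k` are fixed centring constants (defaults 12.0 and 9.2 internal units,
the approximate population intercepts).  Centring is a pure
reparameterisation of h0 — alpha keeps its meaning as a log hazard ratio
per unit of the functional — but it is numerically essential: with hazard
ratios of ~6 per unit and trajectories of magnitude ~12, the uncentred
exponent alpha·eta ≈ 22 would overflow the hazard and lock the sampler
(any proposal on alpha shifts every subject's cumulative hazard by a factor
e^(12·d alpha), which the baseline heights can only re-absorb a Gibbs sweep
later).

### Time basis

Natural cubic spline with 3 degrees of freedom, built from truncated power
functions so that values, time derivatives and running integrals are all
available in closed form (the slope and area associations need them).
Interior knots default to the 33rd/67th percentiles of observed visit
times; the generator's truth basis uses knots at one and two thirds of the
administrative horizon (40 and 80 months of 120).  Columns are rescaled to
unit maximum absolute value over the boundary interval so coefficients are
O(1); beyond the boundary the basis continues linearly.

### Priors

* beta_k, gamma, alpha: independent N(0, 1/0.001) — the stated "0.001" is
  read as a precision, matching the declared intent of vague priors (the
  literal variance-0.001 reading is available via
  `PriorSpec(reading="variance")`).
* residual variances sigma_k^2 ~ InvGamma(shape 1, scale 0.005)
  (equivalently a Gamma(1, 0.005) prior on the precision, the conjugate
  BUGS-style reading).
* baseline heights lambda_j ~ independent Gamma(0.01, 0.01).
* D ~ InvWishart(q + 1, I) with q the total random-effect dimension.

### Sampler

Metropolis-within-Gibbs with exact conjugate updates wherever the model
admits them, and Gaussian-proposal Metropolis-Hastings elsewhere:

* sigma_k^2 and D: conjugate (inverse-gamma, inverse-Wishart given b).
* lambda_j: the cumulative hazard is *linear* in each height, so
  lambda_j | rest ~ Gamma(a0 + d_j, b0 + A_j) exactly, where d_j counts
  events in interval j and A_j integrates exp(gamma'w + sum alpha f) over
  interval j across subjects.  This replaces a random walk on log lambda
  with an exact draw.
* beta_k and the per-subject b_i: Metropolis-Hastings using the exact
  Gaussian full conditional implied by the longitudinal data (and prior)
  as the proposal, so the acceptance ratio reduces to the survival-part
  ratio.  Acceptance rates are typically 0.7–0.95 and the update needs no
  tuning; a plain random walk in 8–12 dimensions mixes far worse at the
  iteration budgets used here.
* gamma and alpha: adaptive random-walk blocks.  A scalar step size
  follows Robbins-Monro toward 0.234 (multivariate) / 0.44 (scalar), and a
  diagonal preconditioner is learned online (Welford running variances)
  during burn-in.  The preconditioner matters: the posterior scales of the
  value and slope association coefficients differ by two orders of
  magnitude, and a shared scalar step collapses the slope terms' effective
  sample size.  All adaptation freezes at the end of burn-in.

The survival integral uses Gauss-Legendre quadrature per baseline interval
intersected with [0, T_i] (default 15 nodes per segment; doubling the node
count changes no subject's cumulative hazard by more than 1e-6 under the
default generator).  Subject-level log-likelihood contributions are stored
per retained draw for WAIC/DIC; DIC's plug-in deviance is evaluated at the
posterior mean of all parameters including the subject effects.

Chains are initialised from a two-stage warm start (per-outcome linear
mixed model for beta, sigma^2, D and the empirical-Bayes subject effects; a
Cox screen for gamma; crude interval event rates for lambda; alpha at 0),
with later chains jittered for overdispersion.  Each chain's random stream
derives from (seed, chain index), so runs are bitwise reproducible.

## Synthetic cohort generator

The generator is the study's data-generating process with known truth:

* Baseline covariates: independent categoricals at the cohort's reported
  prevalences (e.g. diabetes 29.9%, positive proteinuria 31.4%, low HDL
  32.8%); the fraction aged ≥65 is not reported and defaults to 0.25.
  Hypertension duration is drawn Exp(mean 3 y) truncated at 10 y (not
  reported; chosen as a plausible clinic mix).
* Trajectories: fixed effects and random-effect SDs default to the fitted
  longitudinal submodel tables on the internal scale (SBP intercept 11.99,
  DBP 9.19; RE SDs 0.36/0.54/0.89/0.53 and 0.50/0.37/0.77/0.45; residual
  SDs 0.62/0.53).  D is block-diagonal per outcome with an optional
  cross-outcome block (only per-outcome SDs are reported).
* Survival: gamma defaults to the logs of the reported adjusted hazard
  ratios; alpha defaults per structure to the logs of the reported
  association AHRs (6.25/3.75 for SBP value/slope, 4.32/5.64 for DBP).
  Event times invert S(t) = exp(−Λ(t)) at a uniform draw using the same
  cumulative-hazard evaluator as the fitter (bracketed root refinement).
* Observation: quarterly visits strictly before follow-up; observed values
  are eta + noise converted to mmHg; a small per-value missingness
  probability (default 0.002, giving ~9% of subjects at least one missing
  value over a median follow-up); independent exponential loss to
  follow-up (0.008/month) plus an administrative cutoff at 120 months.
* Calibration: the default baseline height 1.28e-4/month was calibrated
  once so the default configuration yields ~14.2% cumulative events and a
  median follow-up near 70 months, the study's reported figures.
* The rare visit where the latent SBP and DBP trajectories cross (the
  default D is diagonal, so nothing prevents it) is floored so that
  recorded SBP exceeds DBP by at least 2 mmHg, mimicking plausibility
  checks in data entry.

What the generator does *not* emulate: informative censoring, competing
risks, calendar-time effects, measurement rounding habits, and any
correlation between baseline covariates.  Passing recovery tests therefore
demonstrate internal consistency of the machinery under the assumed model,
not robustness to the misspecifications real clinic data would add.

## Descriptive survival layer

Person-years and incidence density with an exact Poisson (chi-square) 95%
interval; the cumulative-incidence proportion gets Clopper-Pearson.  The
published incidence interval (1.89–3.14 per 100 PY) is not exactly
reproduced by any standard method we evaluated; the exact-Poisson interval
is reported and the discrepancy left standing.  Kaplan-Meier estimation is
delegated to lifelines, with Greenwood variance and a log-scale band
assembled from the risk table; the log-rank test and the Cox screen
(Efron ties; a Breslow path via direct optimisation) also ride on
lifelines/scipy.  Proportional hazards are checked by correlating
Schoenfeld residuals with event-time rank (per covariate and globally, in
the usual scaled-residual chi-square form, verified against R's
survival::cox.zph during development); goodness of fit by martingale
residuals, which sum to zero at the optimum by construction.  The p ≤ 0.25
bivariable screen is a reporting helper; the joint model's covariate list
is always user-specified.

## Longitudinal submodels

Maximum likelihood (not REML, so AIC/BIC are comparable across fixed-effect
sets) through statsmodels MixedLM behind the `fit_lmm` surface; BLUPs are
computed directly from the fitted variance components (robust to boundary
estimates).  A generalised-least-squares closed form handles the
known-variance case.  Random structures: intercept-only, intercept plus the
first (linear) basis column, or the full spline basis (matching the four
reported random-effect SDs).  `select_random_structure` ranks by AIC,
breaking ties toward fewer parameters and flagging AIC/BIC disagreement.

## Sample-size calculators

Longitudinal: n = 4 (z_{a/2} + z_beta)^2 sigma^2 (1 + (J−1) rho) / (J delta^2);
survival: n = 4 (z_{a/2} + z_beta)^2 / (P theta^2); both round up.  The
default z-values are the two-decimal constants of applied practice (1.96,
0.84), which reproduce the published 393 (SBP) and 249 (DBP) exactly; exact
quantiles (1.95996, 0.84162) are exposed for audit and give 393.35/249.25
before rounding.  The survival formula with its published inputs
(P = 0.176, theta = 0.69) evaluates to 374.3 (rounded z) / 374.7 (exact z),
ceiling 375 — not the published 373; the published z-values or the
precision of P cannot be recovered from the text, so the calculator reports
its own value.  The contingency step max(n) × 1.10 rounds up to 433 either
way.  Whether theta = 0.69 is ln 2 or a literal hazard ratio is ambiguous;
it is treated as the log hazard-ratio magnitude.

## Problem sizes of the stochastic test experiments

The recovery, selection and calibration experiments run at desk scale,
chosen once:

* Recovery: 10 cohorts of 150 subjects under `value_and_slope` with the
  published alpha truths; 2 chains × 4 000 iterations (burn-in 1 000,
  thin 2), 5 quadrature nodes, 6 baseline intervals, and the four
  significant survival covariates (age ≥65, low HDL, diabetes,
  proteinuria) in generator and fitter — at ~22 events a 12-covariate
  survival submodel would be prior-dominated.  The 4-covariate condition's
  baseline height (2.0e-4) was recalibrated to keep the ~14% event
  fraction.
* Selection: the same cohorts; for each of 10 seeds the value-and-slope,
  slope-only and area-only structures are fitted (2 × 1 500, burn-in 600,
  thin 3, shared two-stage warm start) and ranked by WAIC.
* Null calibration: 10 cohorts with alpha = gamma = 0 (baseline height
  1.9e-3 to preserve the event fraction) fitted with the full association;
  plus 200 Cox-only null replicates at n = 1 000 for the Schoenfeld test's
  size.

### A note on slope-association identifiability

Under the trajectory defaults above, the between-subject/time spread of
the quarterly-slope functional is ~0.025 internal units, versus ~0.6 for
the current-value functional.  With ~22 events per scaled cohort the data
carry almost no information about the slope coefficients: their posteriors
under the vague prior are plateaus of half-width ~10–20 around wherever
the weak likelihood drifts, so their posterior *means* are essentially
arbitrary even though their credible intervals are wide enough to cover
the truth.  Point-estimate accuracy for the slope coefficients at this
scale is therefore not attainable under these generating conditions; the
recovery test reports this honestly rather than inflating the generating
slope variance.  A large-cohort check (n = 800, value-only association)
recovers all survival coefficients within their intervals, which localises
the issue to information content, not implementation.

## Numerical choices and edge cases

* Internal outcome scale mmHg/10 everywhere inside the models; conversion
  happens in readers/writers and the generator boundary.
* Visit-to-grid matching tolerance 0.5 months for the complete-case rule;
  unmatched grid points before follow-up count as missing.
* Multiple imputation is simplified to conditional-normal predictive draws
  from the fitted mixed model (exact conditional means when the
  conditional variance vanishes), not chained equations.
* "12 knots" for the baseline hazard is implemented as 12 intervals with
  cutpoints at event-time quantiles; degenerate/duplicate quantiles are
  nudged apart.
* Empty association (`none`), zero-iteration MCMC runs, zero-event
  incidence, and all-censored KM curves are legal and covered by tests.
* Retained draws per chain = (total − burn_in) // thin.
* rank-normalised split-Rhat and bulk ESS via arviz; constant chains get
  Rhat 1.0 by convention and are flagged degenerate.
* WAIC uses the ddof = 1 sample variance in p_waic (arviz uses ddof = 0;
  they agree to ~0.1% at the draw counts used here).  WAIC is the primary
  ranking criterion; DIC is shown alongside.

## Known limitations

* One-dimensional random-walk blocks for gamma/alpha can mix slowly when
  the posterior is strongly correlated with the baseline heights; the
  conjugate lambda sweep mitigates but does not remove this.
* The piecewise-constant baseline with quantile knots is the only h0
  family implemented (no spline log-hazard variant).
* Architecture supports K longitudinal outcomes but tests cover K ≤ 2; no
  competing risks, no dynamic prediction, no informative censoring.
* The complete-case/imputation comparison mirrors the analysis chain's
  sensitivity check; it is not a treatment of non-ignorable missingness.
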