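# Methods

## Scope and data flow

The package analyzes *published* survival evidence: per trial arm, a
digitized Kaplan–Meier curve (time in months, survival probability), a
numbers-at-risk table, and the arm size.  Four stages:

1. **Curve cleaning** — clamp survival to [0, 1], merge duplicate times
   keeping the lower value, clip any later rise down to the running minimum
   (digitization noise is small and one-sided repairs suffice), prepend
   (0, 1).
2. **IPD reconstruction** — interval-based scheme in the style of Guyot et
   al. (2012): within each risk-table interval, iterate a censoring count
   until the end-of-interval at-risk count matches the table, spread the
   censoring times uniformly, and derive event counts from the digitized
   step ratios with nearest-integer rounding whose fractional remainder is
   carried forward across steps and intervals.  Beyond the last risk entry
   the censoring count is chosen to reproduce the reported event total when
   it is known, otherwise a constant censoring rate estimated from the last
   complete interval is assumed; subjects still unresolved at the final
   coordinate are administratively censored there.  Ties place events
   before censorings, the standard KM convention.
3. **Hierarchical fitting** on survival fractions (not on the
   reconstructed event times): the model and estimation are described
   below.  The reconstruction stage serves validation and re-estimation of
   curves on arbitrary grids; fitting consumes curve fractions directly,
   which is what the weighted residual model describes.
4. **Simulation** of medians, landmark rates, percentile bands, VPC/GOF.

## The population model

For study *i* at time *t_ij*:

    Obs_ij = S(t_ij; Te_i, p_i) + eps_ij * SE_ij,  eps ~ N(0, sigma^2)
    Te_i = Te_pop * exp(theta_c * COV_i) * exp(eta_Te,i)
    p_i  = p_pop * exp(eta_p,i),  (eta_Te, eta_p) ~ N(0, diag(omega^2))

* `SE_ij = sqrt(Obs_ij (1 - Obs_ij) / N_ij)` is the binomial standard
  error of the observed fraction.  The number at risk `N_ij` is linearly
  interpolated from the risk table and held constant beyond its last
  entry.  Observations are clamped to [0.005, 0.995] before weighting so
  extreme fractions never get zero variance; the curve origin (t = 0,
  S = 1) is dropped as informationless.
* Covariate coefficients act on `Te` only by default (scale of the time
  axis); support for shape covariates exists but is off.  The race
  covariate is coded as the non-Asian indicator/proportion with Asian as
  the reference, so a positive coefficient lengthens non-Asian survival.
* Random-effect correlation is fixed at zero (diagonal omega), matching
  independent lognormal perturbations per parameter.

### Te/p parameterization

Hazards are classically written with a scale `lam` and shape `gam`
(Weibull `h = lam*gam*t^(gam-1)`, Gompertz `h = lam*e^(gam t)`,
log-logistic `h = lam*gam*(lam t)^(gam-1) / (1 + (lam t)^gam)`).  The
population scale `Te` follows the convention of mixed-effects TTE
software: `p = gam`; for Weibull and Gompertz `Te` solves H(Te) = 1
(`S(Te) = e^-1`; Weibull `Te = lam^(-1/gam)`, Gompertz
`Te = log1p(gam/lam)/gam`); for the log-logistic `Te = 1/lam`, i.e.
`S(Te) = 1/2`, so the median equals `Te` exactly.  This convention — and
only this one — reproduces the published medians from the published
`(Te_pop, p_pop)` values (e.g. Weibull median `Te (ln 2)^(1/p)` = 35.4
months at Te = 41.69, p = 2.25; log-logistic median = Te).  The hazard of
Weibull/log-logistic families diverges at t = 0 when `gam < 1`; the
hazard function returns `inf` there and all likelihood code uses the
cumulative hazard instead.  Time is months throughout.

## Estimation

The marginal likelihood integrates each study's Gaussian observation
density over its two random effects with **adaptive Gauss–Hermite
quadrature**: the conditional mode is found by a batched Gauss–Newton
search (analytic dS/dTe, dS/dp; backtracking line search; gradient
tolerance 1e-7 — the integrand is stationary at the mode, so mode error
enters only at second order), nodes (default 9 per dimension) are centered
there and scaled by the Cholesky factor of the inverse Gauss–Newton
curvature, and the log-integral is accumulated with log-sum-exp.  With an
omega at zero that dimension is pinned and the quadrature drops to 1-D or
to the closed-form weighted Gaussian log-likelihood.  A dense 2-D
trapezoid oracle agrees to 1e-4 on toy sets (tested).

The outer problem maximizes the summed marginal log-likelihood over
`{log Te_pop, log p_pop, theta, log omega_Te, log omega_p, log sigma}`
with L-BFGS-B (finite-difference gradients, step 1e-5 on the transformed
scale; omega bounded in [1e-3, 5]).  Fits are deterministic: same data and
options give bitwise-identical results.  `sigma` is estimated by default
and fixable via `FitOptions.fix_sigma`; with fewer than two studies the
omegas are fixed at zero.  Standard errors come from the inverse of a
central finite-difference Hessian of the negative marginal log-likelihood
in the *natural* parameters (relative step 1e-3); a singular Hessian
flags the SEs as missing rather than failing the fit.  Empirical-Bayes
study effects are the conditional modes at the optimum.

Model selection: AIC = −2LL + 2k with k the count of estimated fixed
effects + random-effect SDs + residual scale; ties break toward fewer
parameters; candidates must be fitted to identical observations (guarded
by a data hash).  Covariates are screened one at a time by the Wald test
(z = estimate/SE, two-sided normal p, threshold 0.05), forward inclusion
without backward elimination.

## Simulation

`simulate_scenario` draws, per replicate, one study-level `(eta_Te,
eta_p)` pair (population variability at the scale of the fitted omegas)
and a covariate stratum per subject, samples event times by inverse CDF,
and summarizes the replicate KM medians and landmark fractions by their
median with 2.5–97.5 percentile intervals.  Defaults: 1000 replicates,
cohort sizes equal to the pooled arm sizes (350 first-line, 408
second-line), landmarks at 12/36/60 months.  A replicate whose curve never
crosses 0.5 is excluded from the median summary and counted (warning above
5%).  Replicates use antithetic eta pairs (replicate 2k+1 mirrors 2k):
each draw keeps its N(0, omega) marginal law, and the pairing roughly
halves the Monte Carlo error of the median-of-medians summary; it can be
switched off per scenario.  Seeding is hierarchical: one scenario seed
spawns independent per-replicate child streams.

`landmark_rate` reports mixture-weighted survival at a horizon averaged
over the random effects (Monte Carlo over eta, default 10,000 draws; exact
closed form when omega = 0 or averaging is disabled).  The
random-effect-averaged rate is the quantity that matches the published
landmark rates — e.g. the 5-year first-line rate is ≈ 23% with
eta-averaging versus ≈ 15% for the typical curve alone, so the published
simulation must have included the between-study variability.

The VPC simulates replicate datasets at the observed design (same
studies, times, at-risk numbers), forms 10/50/90 percentile bands per
observation slot and reports the observed-in-band fraction; GOF reports
population (eta = 0) and empirical-Bayes study-level predictions, R², and
weighted residuals (obs − pred)/SE, which should be ≈ N(0, sigma²) under a
correct model.

Parameter-uncertainty propagation (resampling the fixed effects from
their asymptotic normal) is not implemented; the reported intervals
reflect population variability and cohort sampling only.  The published
CIs are considerably narrower than population-variability percentile
bands, consistent with a parameter-uncertainty interpretation — the point
predictions are unaffected, and the intervals reported here are
percentile-based by construction.

## Synthetic data

The original digitized figures cannot be redistributed, so the generator
emulates their statistical structure: per study, lognormal study effects
perturb the generating model; per subject, a covariate is drawn, an event
time is sampled, and censoring is the minimum of an administrative cutoff
and exponential dropout.  Default conditions: 38-month cutoff (30 for the
second-line arms) and dropout rate 0.008/month, which censor roughly half
of the OS records of a 40-month-median arm — matching the maturity of the
emulated trials; digitization uses 40 points per curve, 6-month risk
tables and uniform ±0.005 survival jitter.  The benchmark bundle mirrors
the emulated design: first-line arms of 279 (62% Asian) and 71 (100%
Asian) subjects, second-line arms of 129 and 279, generated from the
published final-model parameters, plus a 20-study recovery suite
(Weibull Te = 40, p = 2.2, omega = 0.3, sigma = 1, 300 subjects/study)
and a 10-subject hand-checkable fixture.

What passing synthetic tests do *not* show about real data: digitization
error here is uniform and small, risk tables are exact, and arms share a
common observation grid; real figure extraction has correlated,
heteroscedastic errors and sparser risk tables, so real-data deviations
will be somewhat larger than the fixture values.

## Numerical choices and limitations

* Quadrature nodes: 9 per dimension by default (configurable); mode search
  capped at 18 Gauss–Newton iterations with eta clipped to ±30.
* Recovery-simulation problem sizes (20 studies × 10–13 time points, 50
  AIC-selection replicates, 200 Wald-screen replicates) were chosen as the
  smallest designs at which the estimator properties are stable.
* The event/censor split inside a risk-table interval is underdetermined
  by the boundary at-risk counts; reconstruction tracks the curve shape
  first, so the reconstructed event total can drift by ~2–3% of events on
  coarse grids even when the reported total is supplied (the validation
  report carries the residual difference).
* Wald screening at ~20 studies is approximate; its measured type-I error
  on null covariates lies in [0.02, 0.10] (tested), not exactly 0.05.
* With only two arms per treatment line (the emulated design), the
  between-study variances and any trial-level covariate are weakly
  identified — covariate screening on the 2-arm fixtures can attribute
  study effects to the covariate.  Estimator-level guarantees are
  established on the 20-study suite instead.
* Exit codes of the CLI: 0 success, 2 input error, 3 convergence failure,
  4 validation failure.
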