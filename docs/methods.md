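# Methods

## Model

For subject covariates x, treatment indicator z (1 = intensive arm) and
event time T, the fitted hazard is

    λ(t | x, z) = λ₀(t) · exp( η(x) + z · g(η(x)) )

* **Risk score** η(x) = βᵀx̃, with x̃ the design (one-hot expanded
  categoricals) standardized to mean 0, SD 1. β is estimated by maximizing
  the Efron partial log-likelihood minus the elastic-net penalty
  λ[α‖β‖₁ + (1−α)‖β‖₂²/2] (glmnet 1/n scaling) by cyclic coordinate descent
  on the iteratively reweighted quadratic approximation. Defaults α = 0.5,
  λ = 0.01; λ may instead be selected by k-fold cross-validated partial
  likelihood (Verweij–van Houwelingen), with fold assignment seeded.
  KKT stationarity is checked at every returned solution (tolerance 1e-7).
* **Treatment interaction** g(η) = γ₀ + γ₁η + γ₂·rcs(η), a constant
  log-hazard-ratio term plus linear and restricted-cubic-spline (3 knots at
  the 0.1/0.5/0.9 quantiles of η) dependence on the risk score. γ is fitted
  unpenalized by Newton–Raphson with η as an offset; its covariance is the
  inverse observed information and feeds the Wald linearity test on γ₂.
* **Alternation.** (i) β-step: elastic-net Cox with z·g(η_prev) fixed as an
  offset, followed by a one-parameter unpenalized refit of the scale of η
  (a calibration-slope step — see "Design choices"); (ii) γ-step given η.
  Stop when the relative L2 change in η falls below 1e-6 (max 20 rounds).
* **Absolute risks.** Breslow baseline cumulative hazard
  H₀(t) = Σ_{t_g ≤ t} d_g / Σ_{R(t_g)} exp(lp); risk(t*) =
  1 − exp(−H₀(t*)·e^{η + z·g(η)}). The horizon defaults to t* = 4.13 years.
  The estimated risk difference (intensive − standard) therefore tends to 0
  as η → −∞ for any bounded g — the zero-risk constraint is structural.

## Design choices

* **Treatment main effect γ₀ is included.** A through-origin interaction
  (g(0) = 0) was considered and rejected: it cannot represent a constant
  relative treatment effect, and in simulations under a constant hazard
  ratio it forced a spuriously increasing ĝ whose estimated risk
  differences ranked subjects almost inversely to the truth. The zero-risk
  constraint does not require the restriction, because the proportional-
  hazards risk transform already drives the risk difference to zero with
  the risk itself.
* **Calibration-slope refit.** The elastic-net penalty shrinks the scale of
  η as well as selecting covariates. Left uncorrected, the treated arm's
  z·η interaction column absorbs the missing slope (the standard arm has no
  such column), distorting g. Refitting a single unpenalized coefficient on
  η after each β-step restores the scale while keeping the penalized
  direction and sparsity; with λ = 0 the slope is 1 and the step is a
  no-op.
* **Ties** use Efron's approximation throughout (likelihood, gradients,
  information). At tied event/censoring times, events precede censorings.
* **GND test**: χ² = Σ_g (O_g − E_g)²/V_g with O_g the within-group KM risk
  at t*, E_g the mean model risk, V_g the Greenwood variance; groups with
  fewer than 5 events are merged into the adjacent higher-risk group;
  df = retained groups − 1. Both the merge threshold and the grouping count
  are arguments.
* **Calibration deciles** are formed on the pooled cohort (both arms),
  since the score estimates overall outcome risk across arms; the risk
  used is the subject's model risk averaged over the two arm assignments.
* **C statistic** is Harrell's concordance of the risk score (not the
  fixed-time risk); within each arm the fitted risk transform is monotone
  in η, so the two orderings agree.
* **Tertile table**: tertiles of subject-level estimated risk difference
  (most negative = highest benefit); "estimated" is the within-tertile
  median; observed risk differences are KM risks at t* with plain-scale
  normal CIs (RD ± 1.96·√(V_int + V_std)); event counts/percentages are raw
  per-arm counts over follow-up, as benefit-tertile tables are usually
  printed.
* **Magnification curve**: Gaussian-kernel local mean of subject-level
  (standard-arm risk, estimated RD) pairs, bandwidth 0.25 × SD of baseline
  risk; grid spans the 1st–99th percentiles; neighborhoods with essentially
  no kernel mass are reported absent, not interpolated. The 95% band is a
  seeded percentile bootstrap over subjects in which γ and H₀ are refit per
  resample at the fixed converged η — so the band carries the estimation
  uncertainty of the risk difference and widens where data are thin — then
  widened if needed to contain the point estimate. The constant-HR
  reference uses the exact survival-power transform
  RD(r) = (1 − (1−r)^h) − r (slope h − 1 at r = 0); a literal proportional
  line is available via the same function's small-risk limit. The overall
  h comes from a treatment-only Cox fit.
* **Hybrid risk+effect model** adds unpenalized z×subgroup columns (age ≥
  75, female, Black, baseline MCI, baseline CVD by default) to the γ-step
  and compares Harrell's C of the two risk scores.

## Synthetic cohort

The generator emulates the analysis population of a pragmatic
blood-pressure trial with cognitive outcomes:

* **n = 7918** subjects randomized 1:1 (arm independent of covariates);
  **58 covariates** (demographics, social factors, cognitive screening
  scores, vitals, labs, medications) drawn through a Gaussian copula with
  marginals matched to the trial's baseline table; education and usual
  source of care are categorical. The default copula correlation is the
  identity — published sources give marginals only — and any
  positive-semidefinite correlation can be supplied.
* **Truth**: sparse β with 12 nonzero entries (older age strongest risk
  factor; cognitive test scores and employment protective; Medicare/VA
  insurance, creatinine, depression adverse), giving SD(η) ≈ 0.79.
  Four latent components — amnestic MCI, any MCI, probable dementia,
  death — have constant base hazards calibrated once so the composite
  outcomes' per-arm event fractions match the trial's reported counts
  (≈19% intensive / 21% standard for the primary composite over follow-up);
  death's loading on η is 0.8. Component times are independent exponentials
  given η; an outcome's event time is the minimum over its components.
* **Treatment effect**: constant log HR = log 0.85 by default (the trial's
  overall estimate); a linear-in-risk alternative θ(η) = log 0.85 − 0.2η
  provides pronounced, non-crossing heterogeneity for recovery experiments
  (chosen by an oracle-based power calculation to make tertile-ordering
  recovery detectable at n = 8000); arbitrary θ(η) and additive
  subgroup-specific effects are supported.
* **Censoring**: administrative Uniform(3.50, 5.88) years, calibrated to
  the follow-up IQR; optional exponential dropout (default off). Eligibility
  filtering reproduces the trial's flow when no-followup/missingness rates
  are set (e.g., 643/9631 = 6.7% without follow-up assessments).
* **Oracles**: closed-form per-subject absolute risk
  1 − exp(−t·Σ_k λ_k e^{a_k η + z θ(η)}) and risk difference, used as the
  independent reference in tests.

What the generator does **not** emulate: correlated covariates, visit-based
(interval-censored) outcome ascertainment, adjudication error, competing
risks (components are independent, and death is just another component),
informative censoring, or covariate-specific effects beyond the optional
subgroup shifts. Passing tests therefore demonstrate correctness of the
estimation machinery under a proportional-hazards data-generating process,
not robustness to those real-data features.

## Numerical choices and scales

* Coordinate descent: tolerance 1e-7, at most 1e4 sweeps per quadratic
  approximation, outer IRLS stops on max coefficient change < 1e-6;
  weights floored at 1e-10; linear predictors are max-shifted before
  exponentiation.
* Newton fits use step halving and a 1e-12 ridge on the information matrix.
* Degenerate inputs fail loudly: no events, a single treatment arm,
  zero-variance design columns (named), fewer than 30 events for the
  modified model, t* beyond follow-up, non-PSD copula correlations.
* Test and validation problem sizes are scaled for a desk run: recovery
  experiments use n = 8000 with 20 replicates, type-I experiments use
  n = 1000–1500 with 60–500 replicates, closed-form checks use n = 1e5;
  default bootstrap B = 200 (tests use 15–100).
* All randomness flows from named integer seeds (simulation, CV folds,
  bootstrap); identical seeds give byte-identical artifacts.

## Known limitations

* The alternating fit is a block-coordinate scheme; convergence to the
  joint penalized optimum is not guaranteed in pathological cases (it is
  monitored and reported via `n_iter`/`final_rel_change`, with a warning on
  non-convergence).
* The magnification band conditions on the converged η̂; uncertainty in the
  risk-score coefficients themselves is not propagated.
* Discrimination of the default synthetic truth (C ≈ 0.71) is set by the
  chosen β magnitudes; the event-fraction calibration, not the C statistic,
  anchors the generator.
* Normal-approximation CIs for KM risk differences can extend past ±1 in
  tiny strata; a transformed-scale alternative is not implemented.
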