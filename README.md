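# riskmag

Risk-magnification analysis of heterogeneous treatment benefit in randomized
time-to-event trials, with a built-in synthetic-cohort generator patterned on
a large blood-pressure trial's cognitive-outcomes population.

## The problem

A randomized trial reports a single overall hazard ratio — say HR = 0.85 for
intensive vs standard systolic blood-pressure treatment on a composite of
probable dementia and amnestic mild cognitive impairment. But the clinically
actionable quantity is the **absolute risk difference**, and under a roughly
constant relative effect it is *magnified* for patients at higher baseline
risk: RD(r) = (1 − (1 − r)^h) − r for baseline risk r and hazard ratio h.
Identifying who stands to gain the most requires a multivariable baseline
risk model estimated jointly with its treatment interaction.

`riskmag` implements that risk-modeling workflow end to end:

1. **Modified elastic-net Cox model.** The hazard is
   λ(t|x,z) = λ₀(t)·exp(η(x) + z·g(η(x))) with risk score η = βᵀx̃ fitted by
   elastic-net-penalized Cox partial likelihood (Efron ties, cyclic
   coordinate descent, offset support) and treatment log-HR function
   g(η) = γ₀ + γ₁η + γ₂·rcs(η) fitted unpenalized. Fitting alternates a
   penalized β-step (interaction fixed as an offset, followed by an
   unpenalized calibration-slope refit of η's scale) with a Newton γ-step,
   until η stabilizes. Absolute risks at the horizon t* = 4.13 years come
   from the Breslow baseline cumulative hazard; the estimated risk
   difference tends to 0 as η → −∞ by construction.
2. **Adequacy diagnostics.** Harrell's C; decile calibration against
   Kaplan–Meier observed risks with Greenwood variance; mean absolute error
   across deciles; the Greenwood–Nam–D'Agostino chi-square calibration test.
3. **Benefit validation.** Tertiles of estimated benefit with observed KM
   risk differences and 95% CIs; risk-magnification curves (kernel-smoothed
   subject-level RD vs baseline risk, bootstrap 95% band with per-resample
   interaction refits, constant-HR reference line, quartile overlay);
   a Wald linearity test on the spline interaction; and a hybrid
   risk+effect model adding prespecified treatment-by-subgroup interactions.
4. **Synthetic cohort.** 7918 subjects randomized 1:1, 58 baseline
   covariates with trial-like marginals via a Gaussian copula, composite
   cognitive outcomes from exponential component hazards with ~19–21%
   4-year event fractions, administrative censoring Uniform(3.50, 5.88)
   years, and closed-form oracles for every subject's true risks.

## Worked example

```bash
riskmag simulate --n 7918 --seed 1 --out cohort.csv
riskmag fit      --cohort cohort.csv --set full --outcome pd_amci --out fit.json
riskmag evaluate --cohort cohort.csv --fit fit.json --out calib.csv
riskmag magnify  --cohort cohort.csv --fit fit.json --out tertiles.csv
```

which prints (numbers from this exact run):

```
wrote 7918 subjects to cohort.csv
fit converged=True nonzero_beta=37 lambda=0.01
C=0.709 MAE=0.0061 GND p=0.965
tertile  ...  estimated_rd_median  observed_rd  estimated_minus_observed
   high              -0.037095    -0.055759                  0.018664
 medium              -0.019230    -0.009128                 -0.010102
    low              -0.017275    -0.018495                  0.001220
```

Reading: the elastic net keeps 37 of ~64 design columns; the risk score
discriminates (C = 0.709 against this generator's signal strength) and is
well calibrated (decile MAE 0.006, GND p = 0.97, consistent with
calibration). The high-benefit tertile has a median estimated absolute risk
reduction of 3.7 events per 100 treated over 4.13 years, and the observed KM
risk differences agree with the model's estimates to within roughly 0.02 —
the same estimated-vs-observed check the tertile table is built for.
`riskmag run-all` repeats this for all 3 covariate sets × 4 outcome
definitions and renders calibration and risk-magnification figures.

The same analyses run on any user-supplied cohort CSV with the documented
header (id, arm, per-outcome time/event columns, covariates).

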