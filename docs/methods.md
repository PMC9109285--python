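# Methods

## Outcome models

All models are fitted to completers only (participants with an observed
follow-up AUDIT), mirroring the complete-case convention of the original
analysis. For completer *i* in health center *c(i)* the linear predictor
is

    eta_i = x_i' beta + C_c(i),    C_c ~ Normal(0, sigma_c)

with fixed-effect columns intercept, Group (1 = brief intervention),
Sex (1 = female), Education(complete), Education(superior) — reference
level incomplete — and Age in raw years. The primary outcome, risky
drinking at follow-up, is the indicator AUDIT-total ≥ 8 modeled as
Bernoulli(inv_logit(eta)); the secondary outcomes (follow-up AUDIT-total
and AUDIT-C) are Gaussian with the matching baseline score appended to
the covariates.

Priors are weakly informative and centered on the null: Normal(0, 1) on
every regression coefficient and half-Normal(0, 1) on sigma_c and the
residual SD sigma. A "Normal(0, s)" prior written for a standard
deviation is read as half-Normal on the positive scale, the standard
convention when a scale parameter is given a normal prior; `(0, 1)` is
(mean, SD), not (mean, variance). Both prior scales are configurable
(`prior_sd_beta`, `prior_sd_scales`) for sensitivity analyses; defaults
are exactly 1.

Reference levels for sex and education are package conventions (the
group-effect posterior is invariant to them); ages and baseline scores
enter unstandardized. Centers are indexed in order of first appearance —
random intercepts are exchangeable, so the ordering is inferentially
irrelevant but keeps runs deterministic.

### Sign conventions

The modeled event is *risky drinking*, so OR = exp(beta_2) < 1 favors the
intervention. Score effects are reported as reductions, i.e. -beta_2, so
positive reported values also favor the intervention; the underlying
draws keep the intervention-coded sign.

## Posterior computation

Sampling is plain Hamiltonian Monte Carlo on the unconstrained vector
(beta, c, log sigma_c[, log sigma]) with the log-transform Jacobian in
the density. Per iteration the leapfrog step count is drawn uniformly
from {1, ..., round(lambda/eps)} (trajectory length lambda = 1.2,
capped at 64 steps) to avoid resonant trajectories; the step size is
adapted during warmup by dual averaging (target acceptance 0.8, the
Hoffman–Gelman constants) and a diagonal mass matrix is estimated from
the second quarter of warmup, after which step-size adaptation restarts.
Initial positions are uniform on [-1, 1] per coordinate with up to 100
retries for a finite density. Transitions whose energy error exceeds
1000 are counted as divergences and rejected; divergences are reported,
not fatal — with these priors and five centers occasional warmup
divergences are expected.

Random intercepts use the non-centered parameterization C = sigma_c *
c_raw by default: five groups with a weakly identified scale is the
classic funnel geometry. The centered form is available and, given
enough adaptation, produces the same posterior (checked in the tests via
P(beta_2 < 0) agreement within Monte-Carlo error).

The default chain preset runs 4 chains of 6,250 warmup + 6,250 kept
iterations (50,000 total iterations, 25,000 warmup); a per-chain preset
doubles that. Both leave Monte-Carlo error far below the two decimals at
which effect probabilities are reported — the `mc_se` column
(ESS-adjusted binomial SE) makes this visible per probability.
Diagnostics are split-R-hat and bulk ESS (ArviZ), with parameters
flagged above R-hat 1.01; the pipeline exits non-zero on flags unless
`allow_warnings` is set.

## Effect summaries

Cumulative probabilities are computed on pooled chains: P(OR < t) for
t in {1, 0.8, 0.6} on exp(beta_2) draws, and P(reduction ≥ t) for
t in {0, 0.5, 1} (AUDIT-total) and {0, 0.25, 0.5} (AUDIT-C) on -beta_2
draws; thresholds are user-overridable. The reported mean OR is the mean
of the exp(beta_2) draws (the mean of the OR distribution, not exp of
the mean). Credible intervals are central 2.5%/97.5% quantiles. Density
exports bin by the Freedman–Diaconis rule, with a degenerate single-bin
fallback when all draws coincide.

## Frequentist comparison

The contrast analysis is maximum likelihood for the same mixed logistic
model: the marginal likelihood integrates the center intercepts by a
Laplace approximation (per-center Newton inner optimization), maximized
over (beta, log sigma_c) by L-BFGS-B with sigma_c floored at exp(-8) —
numerically the fixed-effects model — and Wald SEs from a
finite-difference observed information at the optimum. Laplace rather
than adaptive quadrature matches common mixed-model defaults at five
clusters; the test suite checks the sigma_c = 0 reduction against
statsmodels' IRLS logistic fit to 1e-6 and the full fit against
`lme4::glmer` (nAGQ = 1). Wald (not profile) intervals are a declared
convention. Estimates beyond |beta| = 15 raise a separation error;
optimizer non-convergence is reported via a flag, not an exception.

## Synthetic-trial generator

The generator reproduces the study's design skeleton: two arms of
174/168, five centers with uniform assignment, baseline AUDIT-total
uniform on the eligibility band [8, 15], and missing-completely-at-random
attrition at rate 0.14 (the original trial retained 294 of 342). The
trial reports no covariate marginals or center sizes, so covariate
defaults are declared, not inferred: sex Bernoulli(0.5), education
proportions 0.3/0.5/0.2 (incomplete/complete/superior), age uniform
integers on [18, 65]. AUDIT-C is derived as a noisy bounded fraction
(0.55) of the AUDIT-total, clipped to [0, 12] and at most the total —
consumption items dominate totals in the 8–15 band, and the item-level
joint distribution is unidentified from aggregate reports.

Follow-up outcomes come in two modes:

- **coherent** (default): AUDIT-total at follow-up is Gaussian around
  `2.1 + 0.6 * baseline + audit_effect * group + C_c` with residual SD
  2.5, rounded and clipped to [0, 40]; risky status is *derived* from
  the simulated score (≥ 8). The regression-to-the-mean slope 0.6 and
  residual SD 2.5 are realistic for six-month AUDIT retest in this band
  and put the control follow-up risky rate near 0.65. With the default
  `audit_effect = -0.74` the implied marginal odds ratio is ≈ 0.65
  (verified by simulation at 50,000 per arm).
- **independent**: risky status is drawn directly from the
  Bernoulli-logit model with `true_log_or` (default log 0.6) and center
  intercepts Normal(0, sigma_c_true = 0.3); the follow-up score is then
  generated conditional on the drawn status (≥ 8 iff risky) so the
  encoding threshold inverts it exactly. This mode makes the fitted
  logistic model literally true and is what the parameter-recovery and
  calibration tests use.

Default true effects (`true_log_or = log 0.6`, `audit_effect = -0.74`,
`auditc_effect = -0.4`) equal the effect sizes the reanalysis is designed
to detect, so default runs exercise the pipeline under the scientifically
interesting alternative. Logit-scale covariate defaults
(1.1, -0.25, -0.15, -0.35, -0.01/yr) are modest, plausible values chosen
once.

What passing tests on these data do **not** show: robustness to
informative dropout (attrition is MCAR by construction), item-level
AUDIT structure, center-size imbalance, or covariate distributions
unlike the declared defaults. The generator validates the *inference
machinery*, not the original data collection.

## Problem sizes in the test suite

Simulation-backed checks are sized to keep the default suite quick while
leaving clear statistical margins: parameter recovery uses 20 replicates
at 2,000 per arm with 2 chains of 600 kept draws (CrI coverage is
assessed against ≥ 18/20); null p-value calibration uses 50 replicates
at the study's own arm sizes; sampler-vs-quadrature agreement uses 4
chains of 2,000 draws against adaptive 2-D quadrature of an exact
12-observation posterior; the covariance detailed-balance check uses
40,000 kept draws. Larger replicate counts only shrink the assertion
margins.

## Known limitations

- Plain HMC with a diagonal mass matrix; no NUTS-style dynamic
  trajectories. Adequate at ~14 parameters, inefficient for much larger
  hierarchies.
- The Laplace ML fit's Wald SE for the group effect conditions on the
  estimated sigma_c (as lme4's `vcov` does); profile intervals are not
  implemented.
- Only complete-case analysis; no imputation of missing follow-up.
- Informative priors beyond scale changes (e.g. evidence-based BI
  priors) are a configuration knob, not a curated library.
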