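# Methods

## The cross-lagged panel model

For paired baseline/follow-up measurements of BMI and serum uric acid (UA),
both preprocessed to z-scores (see below), the model is

    bmi_fu = track_bmi·bmi_base + ρ1·ua_base + γ1·f + e1
    ua_fu  = ρ2·bmi_base + track_ua·ua_base + γ2·f + e2

with `f` the standardized follow-up duration, exogenous covariances free, and
`cov(e1, e2)` fixed at 0. Variables enter as observed scores — no latent
factors, no missing-data machinery (complete cases only).

**Why cov(e1, e2) = 0.** With all exogenous covariances free and both
equations saturated in the exogenous variables, fixing the follow-up residual
covariance is the single restriction that makes the model testable
(df = 1). Leaving it free yields the saturated model (χ² = 0 identically),
which could never exhibit the CFI/RMR values one reports to judge fit. The
restriction is scientifically meaningful — it asserts that, given the
baseline measurements and follow-up time, the two follow-up outcomes are
perturbed by independent shocks — and it is testable: the model χ² *is* its
test. The choice is exposed as `residual_cov_free=True` for the saturated
variant.

**Estimation.** The model is recursive with uncorrelated errors, so the ML
point estimates equal equation-wise OLS; the implementation fits each
equation by OLS (t-based SEs and p-values, residual df per equation) and then
assembles the model-implied covariance Σ̂ explicitly to compute the ML
discrepancy

    F_ML = ln|Σ̂| − ln|S| + tr(S·Σ̂⁻¹) − p,   χ² = (n−1)·F_ML,

with S the (n−1)-denominator sample covariance. The OLS↔ML equivalence is
not assumed — the test suite checks it against a brute-force numerical
maximizer of the full multivariate-normal likelihood over *all* free
parameters (exogenous Cholesky factor, six paths, two error variances) on
tiny panels, to 1e−5.

**Fit indices.** CFI = 1 − max(χ²_m − df_m, 0)/max(χ²_b − df_b, χ²_m − df_m,
0) against the independence (diagonal-covariance) baseline; RMR is the root
mean square of the unique residual covariances, which equals SRMR on
standardized inputs. Good fit is flagged by the conventional rule CFI > 0.90
and RMR < 0.05. Fits refuse panels with n < 30 by default (`min_n` lowers
the floor for algebraic checks only, where SEs and indices are meaningless).

**Stratum comparisons.** Differences in ρ1 or ρ2 between two independent
strata are tested by Fisher's r-to-z:
z = (atanh c₁ − atanh c₂)/√(1/(n₁−3) + 1/(n₂−3)), two-sided normal p. Treating
standardized path coefficients as correlation-scale quantities is an
approximation (they are regression, not product-moment, coefficients); it is
the field's customary shortcut and is documented as such.

## Preprocessing

Order of operations, applied per race×sex stratum:

1. **Medication adjustment** (+10 mmHg SBP, +5 mmHg DBP for treated
   subjects) — only when BP is analyzed as a continuous variable. The
   dichotomous hypertension outcome (SBP ≥ 130 or DBP ≥ 80 or on
   medication) uses recorded pressures, because the flag already enters the
   definition.
2. **Complete-case filtering** with a logged dropped-row count.
3. **Residualization** of each of the four panel variables on the
   cohort-type covariates (children: age; adults: age, smoking, drinking as
   0/1) by within-stratum OLS; constant covariate columns degrade to
   intercept-only centering.
4. **Z-standardization** (sample SD, n−1) within stratum.

Residualize-then-standardize is the canonical order; reversing it gives
different output (residualization changes the scale that standardization
divides out), and a test pins the difference. Follow-up years are *not* a
residualization covariate — they enter the SEM directly as the γ paths.
The composition is invariant to affine rescaling of any raw variable
(unit changes cannot alter results).

In the mediation analyses, covariates are instead included directly in each
regression (age, race and sex indicators in children; plus smoking and
drinking in adults): the two analyses deliberately mirror the two common
adjustment styles, and the code keeps them separate.

## Mediation decomposition

Exposure X (BMI), mediator M (UA), outcome Y (SBP, DBP or hypertension).
X, M and continuous Y are z-standardized on the full sample before fitting so
all coefficients are standardized regression coefficients; covariates stay on
their natural scale. Four steps: c from Y~X; β1 from M~X; β2 and c′ from
Y~M+X (identical covariate set in all three); β_Ind = β1β2 and mediation % =
100·β_Ind/c (undefined when |c| < 1e−12). With a continuous outcome the OLS
additivity identity c = c′ + β1β2 holds to machine precision and is asserted
at 1e−10.

SE(β_Ind) uses the Sobel delta-method formula; its normal-reference p-value
is conservative near the null (the product of two near-zero normals is not
normal), so a seeded percentile bootstrap (default 1000 resamples) is
available and is on by default for the binary outcome. Binary outcomes use ML
logistic regression on the log-odds scale; the additivity identity is *not*
asserted there — logistic coefficients are non-collapsible, so c and
c′ + β1β2 differ even without confounding — and the proportion mediated is
interpreted on the log-odds scale with that caveat. A probit-style latent
variant was considered and rejected: with no stated scale convention, the
log-odds scale keeps coefficients interpretable as odds-ratio logs.

Subgroup differences in (c, c′, β1, β2) are Wald tests of group×X (or
group×M) interaction terms in pooled models with a group main effect;
differences in mediation % use a grouped bootstrap.

## The synthetic cohort generator

The generator is the structural twin of the two analyses, not a replica of
any real cohort. Per subject:

* standardized baseline latents (zx, zu) bivariate normal, correlation
  `r1_gen` (in the cross-sectional design zu = β1·zx + e, i.e. `r1_gen`
  doubles as the generative β1);
* two-wave follow-up latents from the cross-lagged equations with error
  variances chosen to keep every latent at unit variance (stationarity), so
  generative paths are directly comparable with fitted standardized paths;
* raw BMI/UA = stratum mean + linear covariate effects + stratum SD × latent;
* standardized true SBP = cprime_gen·zx + beta2_gen·zu + noise (unit
  variance), mapped to the stratum mmHg scale; DBP the same with paths
  attenuated by 0.6;
* antihypertensive treatment with probability 0.5 when true SBP ≥ 140 or
  DBP ≥ 90; recorded pressures of treated subjects are true − (10, 5) mmHg,
  so the medication adjustment inverts the masking exactly (a test asserts
  the round trip).

Configurations are validated up front: any path outside (−1, 1), a
non-positive implied error or noise variance, a negative SD or an
out-of-range probability raises a configuration error naming the offending
parameters.

**Default conditions.** Stratum means/SDs for age, BMI, UA, SBP, DBP and the
smoking/drinking prevalences follow the published descriptive tables of the
two-wave (children n=564, follow-up 7–14 y; adults n=911, 5–14 y) and
cross-sectional (children n=3102; adults n=3402) cohorts this package
models; composition defaults to 65% White, 50% female. Cross-lagged defaults
use the published point estimates ρ2 = 0.145 (children) / 0.068 (adults) with
ρ1 = 0; tracking (0.7/0.5 children, 0.8/0.6 adults) and synchronous
correlation (0.25) are not printed in the source figures and were fixed once
to respect the reported ordering (BMI tracking > UA tracking > synchronous).
Mediation defaults use the published standardized paths (children β1=0.365,
β2=0.076, c′=0.289; adults 0.322/0.105/0.212). Covariate effects on BMI/UA
and the follow-up-duration effects default to 0 so stratum moments are exact;
tests switch them on to exercise residualization and the γ paths. Follow-up
years are Uniform(min, max).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sampling weights, attrition, assay and
measurement error, non-Gaussian tails (UA and BMI are right-skewed in
reality), age-dependent variance, and any confounding structure beyond the
configured linear covariate effects. Parameter-recovery results show the
estimators are correct under the stated model, not that the model is correct
for any particular cohort.

**Numerical guards.** Raw values are clipped to positivity/physiologic
ranges (BMI ≥ 1 kg/m², UA ≥ 0.1 mg/dL, SBP ∈ [40, 300], DBP ∈ [20,
SBP − 10] mmHg). The guards sit > 4 SD outside every default stratum mean so
clipping is vanishingly rare and does not attenuate paths; the DBP ceiling of
SBP − 10 keeps recorded DBP < recorded SBP even after medication masking
(which lowers SBP by 5 mmHg more than DBP).

**Exact-moment sampling.** Worked examples that must reproduce specified
standardized paths exactly use a sampler that whitens an i.i.d. Gaussian draw
empirically and re-colours it with the Cholesky factor of the target
correlation matrix, making the *sample* moments exact; fitted OLS paths then
equal the targets to machine precision. These samples are synthetic
constructions for arithmetic checks, not simulations.

## Problem sizes used in the shipped checks

Monte-Carlo calibration in the test and acceptance suites uses 200
replicates of n = 5000 for parameter recovery (recovery bands: 3 replicate
SEs of the mean) and 500 replicates of n = 400–500 for null calibration
(band: 0.05 ± 3 binomial SEs). These sizes put the Monte-Carlo SE of a
recovered path near 0.001 — an order of magnitude below the effects being
recovered — while keeping a full run in tens of seconds on one CPU.

## Known limitations

* Two waves and two variables only; no ≥3-wave models, latent variables,
  FIML, or robust/sandwich SEs.
* Fisher Z on path coefficients is approximate (see above).
* Mediation is the classical product-of-coefficients decomposition; no
  exposure–mediator interaction or counterfactual (natural effects)
  framework, no multiple mediators, no longitudinal mediation.
* Descriptive-table tests use pooled-variance t and chi-square without
  continuity correction, and no multiple-testing adjustment (flags are raw
  p-values, matching the table-footnote convention they mirror).
* The duration subgroup split is at the cohort median (half-open), recorded
  in the run log.
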