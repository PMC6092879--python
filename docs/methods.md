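# Methods

## Model

`metatraj` fits a joint multivariate latent growth curve model for seven
metabolic measures over four clinical phases. Each measure has person-level
random growth factors (intercept/slope, plus a quadratic term for BMI and
glycaemia); glycaemia is a second-order ("curve of factors") construct whose
first-order phase values are measured by FPG, 2-h glucose and HbA1c. The BMI
intercept and slope are exogenous and feed the other measures' growth factors
through structural regressions; the endogenous growth-factor disturbances are
freely correlated. Baseline covariates (five 0/1 indicators plus centred
baseline age) shift the growth-factor means, and the glycaemic indicators
carry observation-level adjustments for age-at-phase, sex, ethnicity and
family history of diabetes.

Assumptions worth stating explicitly:

- **Linear-Gaussian throughout.** Conditional on covariates, the 26 observed
  values are multivariate normal with covariate-affine mean and a shared
  covariance. Skewness of real glycaemic measures is not modelled.
- **Discrete common time.** All participants are scored at phase times
  0, 0.6, 1.1, 1.6 (decades). Individually varying examination times are out
  of scope; decade coding keeps quadratic terms well scaled.
- **Measurement invariance over time.** Indicator loadings, indicator
  intercepts and residual variances are phase-constant; the latent glycaemia
  disturbance variance ω is common across phases.
- **Missing at random.** FIML uses each participant's observed sub-vector;
  validity requires missingness to depend only on observed quantities.

## Identification

- FPG is the reference indicator of latent glycaemia: λ_FPG = 1, ν_FPG = 0,
  fixing the latent metric to mmol/L of fasting glucose.
- The HDL-slope ← BMI-slope path is a structural zero (not identifiable in
  this model class), as is any path into the BMI or glycaemia quadratic term.
- A covariate that enters the indicator-level adjustments cannot also load on
  the glycaemia *intercept* factor: the two parameterizations generate
  identical means (indicator terms absorb a g0 shift through the loadings;
  for age, the slope intercept absorbs the elapsed-time drift), so the
  corresponding entries of the g0 row of Γ_f are structural zeros. With these
  constraints the model has 166 free parameters and a positive-definite
  Fisher information at the packaged defaults.
- The BMI quadratic factor b2 is random by default; `ModelSpec(b2_random=False)`
  fixes its variance to zero for smaller samples.

## Estimation

The observed-data log-likelihood groups participants by missingness pattern;
patterns with equal observed counts are evaluated in batched linear algebra.
The value is identical to naive per-participant evaluation (tested to 1e-10).
A singular restricted covariance returns a −∞ sentinel so the optimizer can
retreat.

Optimization runs in an unconstrained packed space: log variances and
log-diagonal Cholesky factors for Ψ_b and Ψ_ζ, so every real vector is a
valid parameter set. Gradients are exact to floating point: the closed-form
gradient with respect to the moment structure is chained through a
complex-step Jacobian of the (data-free) moment map. Because the packed
parameters mix scales from mmHg variances to per-year covariate effects,
L-BFGS-B is run in coordinates whitened by the Cholesky factor of the exact
Fisher information at the starting value — without this the search needs an
order of magnitude more iterations. Multi-start (default 3, jittered) guards
against local optima. Convergence requires scipy's relative-change criterion
(default 1e-8) or a per-participant projected-gradient norm below 1e-4 in the
whitened metric; non-convergence is flagged and warned, never silent.

Standard errors come from the inverse information matrix, delta-method-mapped
to the natural scale. The default is the *expected* (Fisher) information,
which is exact and closed-form per missingness pattern (mean block
`kron(Σ⁻¹, X'X)`, covariance block `n_p/2 kron(Σ⁻¹, Σ⁻¹)`) and positive
definite whenever the model is identified; `method="observed"` inverts a
numerical Hessian instead (central differences of the analytic gradient).
The two agree at optima and are cross-checked in the test suite; the expected
form is the default because finite-difference noise at moderate n can make
the observed Hessian spuriously indefinite.

### Reference models and fit indices

The unrestricted (H1) model is the multivariate regression of the 26
outcomes on the covariates with unstructured residual covariance — the frame
in which the structured model is nested, so the likelihood-ratio chi-square
is non-negative. It is fitted by an EM algorithm with closed-form M-steps
(exact ML; with complete data the first iteration returns the divisor-n
sample moments). The independence baseline (free means and variances, zero
covariances) has a closed-form per-variable solution.

SRMR includes mean residuals (the covariate-driven mean structure is central
here): covariance residuals standardized by the unrestricted SDs, mean
residuals evaluated at the average covariate profile, RMS over the p + 
p(p+1)/2 unique elements, computed against the FIML-unrestricted moments
rather than pairwise-complete moments for consistency with the estimation
frame. CFI uses `1 − max(χ²_M − df_M, 0)/max(χ²_B − df_B, χ²_M − df_M, 0)`,
truncated to [0, 1]. Conventional cut-offs (SRMR 0.08, CFI 0.95) are exposed
as classification helpers.

## Simulator and synthetic cohort

The simulator draws growth factors through the structural paths, adds
per-phase latent-glycaemia disturbances and measurement residuals, and emits
all available measure-phase values; its empirical moments match the
closed-form implied moments (tested at 200,000 draws within 1% on the
standardized scale). The replicate design defaults to 100 trajectory sets
conditional on a fixed baseline table; each replicate's stream derives from
`(seed, replicate)` so any replicate is reproducible in isolation.

Clinical-alert censoring removes all observations at phases strictly after
the first phase at which any thresholded measure meets its cut-off; the
alerting observation itself is retained (it was recorded before any
intervention could act). Default thresholds are conventional referral levels
— FPG ≥ 7.0 mmol/L, 2-h glucose ≥ 11.1 mmol/L, SBP ≥ 160 mmHg,
TC ≥ 7.8 mmol/L — configurable because the source study's actual alert
criteria are not public.

The synthetic cohort generator emulates the structure, not the exact
marginals, of a 1980s occupational cohort: ~0.67 male, 0.09 non-white,
baseline ages uniform on 41–61 (recruitment span 35–55 shifted by ~6 years
to the clinical baseline), independent covariate draws. Missingness composes
monotone visit dropout (per-phase hazards) with item-level MAR deletion whose
logit depends on the previous phase's *observed* values; participants left
with no clinical data are dropped, and every step is counted in a provenance
record. Phase spacing is fixed; per-participant timing jitter is deliberately
excluded to match the discrete-time model.

What passing tests on these data do and do not show: they demonstrate that
the estimator recovers the generating mechanism of a correctly specified
linear-Gaussian cohort with MAR missingness. They cannot show robustness to
skewed glycaemic distributions, informative (MNAR) dropout, time-varying
measurement properties, or real alert-censoring mechanisms, none of which the
generator produces.

## Parameter file and study-condition choices

The packaged defaults embed the published structural paths (e.g. glycaemia
intercept ← BMI intercept 0.2620) and indicator-level covariate coefficients
as generating truth; factor means are set so a zero-covariate profile has
realistic baselines (BMI 25 kg/m², FPG 5.3 mmol/L, SBP 120 mmHg, TC 5.8,
HDL 1.4 mmol/L), and variance components are plausible for a middle-aged
cohort (BMI SD 3.5 kg/m², SBP intercept SD 11 mmHg, slope SD 5 mmHg/decade).
One consequence of combining the published path coefficients with a
realistic BMI variance is that the implied TC and HDL marginal SDs are
larger than clinically typical, and simulated HDL can occasionally go
non-positive; such records are reported as unscoreable by log-link risk
scores rather than silently scored. A second consequence is an
identification asymmetry: the glycaemia, TC and HDL paths are estimated
precisely at a few thousand participants, while the SBP paths have large
sampling SEs (the SBP disturbance variances dominate the BMI-driven signal),
so their recovered values scatter widely around the generating truth; the
recovery checks therefore use replicate-based Monte-Carlo bands.

## Risk scores

Score definitions are JSON documents (terms with input, transform, optional
unit scale and center, sex-specific or common coefficients; Cox-type or
logistic link), so the validation machinery is score-agnostic. Packaged:
the 2008 general-CVD Framingham equation (lipids converted mmol/L → mg/dL;
untreated-SBP coefficients, as treatment is not modelled; diabetes defined
as FPG ≥ 7.0 mmol/L), and two explicitly synthetic logistic diabetes scores
(FPG-based and 2-h-glucose-based) that are constructed stand-ins, not
transcriptions of a published equation — replace them for substantive use.
Validation summaries follow a replication-table layout: simulated means/SDs
pool participant-replicate scores; correlations between observed and
simulated scores are computed per replicate and then averaged.

## Problem sizes

The test suite and acceptance script size their computations as follows:
parameter recovery fits one cohort of n = 1500 (script: 4000) with 10%
item-level MAR and compares against Monte-Carlo bands from 12 replicate fits
at n = 500; SE calibration uses 40 replicate fits at n = 400 (enough to pin
the empirical SD to ~11% relative error against a 25% agreement band);
moment consistency uses 200,000 draws. A preconditioned fit at n = 1500
takes a few seconds on one CPU.

## Known limitations

- No robust (sandwich) SEs, multiple-group models, ordinal indicators, or
  Bayesian estimation.
- No continuous-time or individually-timed observation support.
- HbA1c enters only at the last two phases; its parameters lean on
  cross-indicator covariances and are the least well determined part of the
  measurement model.
- The exclusion-cascade summary reports percentages of the recruited total;
  the published exclusion steps overlap, so counts do not telescope to the
  final sample and no attempt is made to reproduce the overlap structure.
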