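# Methods

## Setting and estimand

The package targets a cross-sectional question: in asymptomatic
(ACVIM stage-B1) small dogs with myxomatous mitral valve disease, how do
13 morphometric measurements (exposures) influence nine
echocardiographic indicators of disease severity (outcomes), net of the
demographic covariates — age, sex, body weight, coat — that plausibly
drive both anatomy and disease?  Exposures are continuous and mutually
correlated, so the adjustment uses a *generalized multivariate
propensity score*: a model for the joint conditional distribution of the
exposure vector given the covariates, rather than a scalar treatment
probability.

## Cohort schema and closed-form derivations

Each record carries demographics, clinical grades, raw echocardiographic
measures and the 13 measurements (cm; the stop angle in degrees).
Derived quantities are exact formulas:

* **Allometric indexing.** Valve and annulus measures are indexed to
  body weight as `raw / BW^b`, with measure-specific exponents
  b = 0.37 (AMVL), 0.41 (AMVW), 0.78 (AMVA), 0.37 (MVAd), 0.40 (MVAs).
* **Jet grading.** The regurgitant jet, expressed as the percentage of
  the left atrial area (ARJ/LAA), is graded 0–5: absent; trivial
  (< 10 %, not all systoles); trace (< 10 %, all systoles); mild
  [10, 30); moderate [30, 70); severe (≥ 70).  The inclusivity of the
  10/30/70 cuts is not fixed by convention anywhere, so the package uses
  lower-inclusive, upper-exclusive bins — a gapless partition — and a
  0 % jet is "absent" regardless of the all-systoles flag.  The severe
  grade is implemented even though screening cohorts of stage-B1 dogs
  rarely contain one.
* **Prolapse grading.** Leaflet position relative to the pivotal-point
  (P) and atrial (T) reference lines maps to 0–3 (none, below P,
  between P and T, beyond T).
* **Severity score.** `(MVP grade + jet grade) · 5 / age`, decreasing in
  age so that equal degenerative change in a younger dog scores as more
  severe disease.  The Table-coded 0–4 jet grade (trivial/trace split)
  enters the score, not a 1–5 clinical scale.
* **Body indexes.** cephalic = 100·HW/HNL (HNL = HL + NL held as an
  exact sum), craniofacial = NL/HL, thoracic = 100·TW/TH,
  height-thorax = 100·TH/WH, volume = 100·BW/WH, body size = 100·WH/BL.
* **Eligibility flags.** Stage B1 requires LA/Ao < 1.6 *and* normalized
  LV diastolic dimension < 1.7 (either at threshold counts as
  enlargement); a sphericity index < 1.65 flags an abnormally spherical
  ventricle.

Missing numeric cells are legal in the CSV interchange format (empty
field), propagate as NaN, and are handled downstream by complete-case
subsetting; no imputation is attempted.

## Synthetic cohort generator

Because the motivating cohort data are not public, validation rests on a
generator with exact ground truth.  Covariates: age ~ gamma with shape
and scale solved (Brent root-finding) so the median is 4.16 y and the
IQR-width-to-median ratio matches the reported 2.91–6.00 y spread;
weight ~ normal(9.15, 1.80²) truncated above 4 kg; sex ~ Bernoulli(0.75
female); coat ~ categorical with 68 % Blenheim; neuter status and BCS
are generated but take no part in inference.  Exposures:
x = μ + A·c + ε with μ the reported measurement medians, c the centred
covariate vector (standardized age and weight, centred sex and Blenheim
indicators), and ε multivariate normal with an exchangeable correlation
of 0.3 (anatomical measures co-vary; no reference covariance is available to
match) and variances chosen so total spreads reproduce the reported
IQRs.  Continuous outcomes: y = b₀ + B·(x − μ) + Γ·c + e on the indexed
scale, back-transformed to raw echo measures by multiplying with BW^b.
Ordinal outcomes: latent B·(x − μ) + Γ·c + logistic(0,1) cut at
thresholds matched to the reported category frequencies; the raw ARJ/LAA
percentage and all-systoles flag are then drawn consistently with the
generated grade, so the grading code is exercised end to end.

**Confounding strength.**  The generator's stated purpose is to produce
*detectable* confounding bias that the weighting step then removes, so
its loadings were calibrated by design simulation: weight loads 0.15 SD
on every measurement, sex −0.10 SD, and age loads 0.30 SD on head length
alone, with a direct age effect on the indexed AMVL outcome (0.50
outcome-SD) and on the jet latent (0.8).  Concentrating the age channel
on one exposure gives a designated coefficient (HL → AMVL_i) whose
unweighted estimate is biased by ≈ 3 robust SEs at n = 400, while
keeping the 13-dimensional density-ratio weights well behaved (effective
sample size ≈ ½ n, mean weight ≈ 1, 95 % CI coverage ≈ 0.94).  Stronger
loadings (≈ 0.45 SD per covariate) were examined and rejected: they push
the density ratio into a heavy-tailed regime where the weighted
estimator is practically unusable at cohort scale (effective sample size
< 20 % of n and visible bias even with oracle weights) — a real
limitation of generalized propensity weighting with many continuous
exposures, documented here rather than hidden.  Default effect sizes B
encode the qualitative pattern of interest (e.g. HL → jet −1.0 per SD on
the latent scale; HL → AMVL_i +0.4 SD) and are the package's own
choices.

What the generator does *not* emulate: measurement error in the echo
operator, litter/pedigree structure, informative missingness, and any
non-Gaussian exposure tails.  Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data features.

**Ground truth densities.** The conditional exposure density is the
exact multivariate normal used for generation.  The "true marginal" is
the Gaussian with the exact first two marginal moments
(μ + A·E[c], A·Cov(c)·Aᵀ + Σ); with nonzero confounding the true
marginal is a non-Gaussian mixture, but any numerator depending on x
alone yields weights that break the x–c association, so this choice is
valid for the balance and bias oracles (and is exact when A = 0, where
every oracle weight equals 1).

## Propensity model and weights

The conditional model is a multivariate least-squares regression of the
13 exposures on an intercept, age, weight, a female indicator, and a
Blenheim-vs-other coat indicator (coat is collapsed because non-Blenheim
cells are small), optionally augmented with bivariate covariate
products.  The residual covariance uses the n − k divisor.  Zero-
variance covariate columns are dropped (they duplicate the intercept);
a genuinely rank-deficient design raises an error naming the collinear
terms.  Interaction screening fits, per exposure and covariate pair,
the small model `exposure ~ u + v + u·v` and returns pairs whose product
term is significant at α = 0.05 (a screening default; the package
exposes it) in any exposure model.

Weights are `exp(log f̂(x) − log f̂(x | c))` with both densities
multivariate normal — marginal moments from the sample, conditional
moments from the model.  An optional log transform of the exposures and
an optional ridge term for near-singular covariances are available, and
symmetric percentile truncation (e.g. 1/99) is off by default.
Model selection computes, for each candidate propensity model, the mean
absolute *weighted* covariate–exposure Pearson correlation and picks the
smaller; exact ties go to the additive model.

Positivity is checked geometrically: a point is inside the convex hull
of the observed exposure vectors iff it is a convex combination of them,
decided by linear-programming feasibility.  With ~50 subjects in 13
dimensions every facet-based hull is degenerate, so by default the test
runs in the leading 5-dimensional principal-component subspace (the
dimension is configurable up to the full 13, which the feasibility
formulation handles) alongside per-exposure observed ranges.

## Outcome models and inference

Continuous outcomes use weighted least squares; the robust covariance is
the HC0 sandwich with weights treated as fixed,
`(XᵀWX)⁻¹ (Σ wᵢ²eᵢ²xᵢxᵢᵀ) (XᵀWX)⁻¹`, i.e. the uncertainty of the
estimated propensity model is ignored — a deliberate, documented
limitation.  Ordinal outcomes use a weighted cumulative-logit
(proportional-odds) likelihood maximized by BFGS with analytic
gradients; cutpoints are parameterized as a first threshold plus
log-increments so they remain ordered, exposures are standardized
internally for conditioning and the estimates mapped back, and the
sandwich uses the inverse numeric Hessian as bread and the outer product
of weighted analytic scores as meat.  Two observed categories reduce
exactly to weighted binary logistic regression; unobserved category
labels are merged downward with a logged warning.  All 13 exposures
enter every outcome model simultaneously; p-values are two-sided normal
approximations with no multiplicity correction.

Diagnostics: D'Agostino normality and a Breusch–Pagan score test on the
√w-scaled residuals, a RESET linearity check, and variance-inflation
factors (flagged as unbounded under exact collinearity) for the linear
fits; surrogate residuals for the ordinal fits — a latent logistic value
sampled (seeded, 1 replicate by default, averaging optional) from the
fitted distribution truncated to the observed category's interval, minus
the linear predictor.  Under correct specification these have mean ≈ 0
and no trend in the predictor or exposures; proportionality violations
appear as *nonlinear* residual–exposure trends, which the test suite
summarizes by the correlation with the squared exposure.

**Index effects.** Composite indexes are ratios s·N/D of measurements,
so their effect on an outcome is obtained by reparameterizing along a
stated direction at an evaluation point (cohort medians by default):
varying the numerator with the denominator fixed gives
∂Y/∂I = β_N·D/s (e.g. thoracic index: β_TW·TH/100), varying the
denominator with the numerator fixed gives −β_D·D²/(s·N); both variants
are reported because neither is canonically "the" index effect.  Where a
sum appears (HNL = HL + NL) the components move in proportion to their
share at the evaluation point.  Standard errors propagate the robust
covariance through the (locally linear) gradient, so for linear
combinations the delta SE is exact.  The volume index involves body
weight, which is a covariate rather than an exposure, so only its
denominator (WH) variant exists.

## Pipeline defaults and numerical choices

Complete cases across exposures, covariates and all nine outcomes define
the analysis set (mirroring a cohort where a few subjects lack some
values); exclusions are listed by id.  The propensity variant policy is
`auto` (screen, fit both, select by balance).  Quantiles use linear
interpolation throughout.  Ordinal optimization starts at β = 0 with
cutpoints at the weighted empirical cumulative logits; non-convergence
raises with the iteration count and gradient norm, and |linear
predictor| > 30 flags probable separation.  Report bundles embed the
package version, a config hash and the seed, and contain no timestamps,
so a run is byte-reproducible.

## Validation problem sizes

The simulation-backed checks use sizes chosen to make the Monte-Carlo
noise small relative to the tested margins while keeping the default
suite fast: 2000-dog cohorts for distributional and balance checks
(median standard errors ≈ 0.03 SD), 500 replicates of 400-dog cohorts
for coverage (binomial SE ≈ 1 %), 200 of those for the bias-reduction
rate, 100 null cohorts (all exposure effects zero, confounding retained)
for the pipeline-wide type-I rate pooled over 117 coefficient cells per
cohort, and 50 cohorts of 500 dogs for detecting the built-in
head-length → jet effect.  The full suite runs in well under a minute on
one CPU.

## Known limitations

* Sandwich errors condition on the estimated weights; coverage is
  slightly anti-conservative in small samples (≈ 0.94 at n = 400 for the
  designated coefficient) and would degrade under stronger confounding.
* Gaussian conditional/marginal densities are an assumption, not a fit
  diagnostic; heavy-tailed exposures would call for the log-transform
  option or a different density family.
* Ordinal effects are non-collapsible: weighted proportional-odds
  coefficients are attenuated relative to the latent data-generating
  slopes when outcome-side covariate effects exist, so ordinal ground-
  truth checks are formulated on sign/significance or on data simulated
  from the pure proportional-odds model.
* With ~50 subjects and 13 exposures, multicollinearity among
  measurements is expected; VIFs are reported and a one-exposure-at-a-
  time sensitivity mode is available through the exposure list in the
  run configuration.
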