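# Methods

## The problem setting

A sequential mixed-meal challenge produces, per participant, timed glucose and
TG concentration curves (0–360 min; meals at 0 and 240 min) and inflammation
markers (IL-6, GlycA) at 0/4/6 h. The scientific questions this package
operationalizes are: which features of the glycemic and lipemic responses track
the postprandial inflammatory response; how well can postprandial GlycA be
predicted from curve features; and how much of an adiposity effect on
inflammation is mediated by TG metabolism, assessed observationally (path
analysis) and genetically (two-sample and network Mendelian randomization).

## Curve features

Features are defined on sampled time points only — no interpolation or
smoothing. The incremental AUC is the trapezoid area of
max(value − fasting, 0), i.e. excursions below the fasting baseline contribute
zero (a signed net-area variant is available via `positive_only=False`);
clipping is applied at the sampled points, so the integrated curve is the
piecewise-linear interpolant of the clipped increments. Peak windows are
closed: first glucose peak [0, 120] min, second [240, 360] min, TG maximum
[0, 360] min; ties at a maximum resolve to the earliest time (this affects
only the reported peak time). Peak times are computed and emitted but excluded
from default model inputs. Required sample times (30/60/120 min for glucose,
240/360 min for TG) are validated and missing ones reported by name.

## The synthetic cohort

The generator is a linear-Gaussian system on standardized latents, dressed in
realistic units, with defaults chosen to match the operating point of a
~1000-person mixed-meal study:

* **Curves.** Concentration = participant baseline + Σ peak amplitudes ×
  Gaussian bumps + per-sample measurement noise, clipped positive. Glucose:
  baseline N(4.91, 0.51) mmol/L, breakfast peak (amp 2.6 ± 1.2 at 40 min,
  width 16 — narrow enough that the meal response does not bleed into the
  fasting draw) and lunch peak (amp 1.56 ± 1.4 at 300 min, width 35), which
  reproduces a ~7.0 mmol/L first-peak mean at 30 min and ~6.5 mmol/L second
  peak. TG: baseline N(1.05, 0.53) mmol/L with one late peak (amp 1.12 ± 0.85
  at 290 min, width 80), giving a ~2.1 mmol/L maximum at 5 h that stays
  elevated (~1.9) at 6 h. The TG peak is deliberately asymmetric about the
  240/360-min pair: a peak exactly midway would make the 4-h and 6-h TG values
  statistically identical and the "matching-time" feature unidentifiable.
* **Planted path.** Standardized slopes: VFM → fasting TG 0.30; fasting TG →
  GlycA 0.70; VFM → GlycA directly 0.17; fasting GlycA → 6-h GlycA 0.30;
  realized 6-h TG → 6-h GlycA 0.70; realized first glucose peak → 6-h GlycA
  0.15. Six-hour GlycA is built from the *realized* curve features
  (standardized by their population-implied location/scale), so the planted
  coupling is to what the meal actually did, and downstream feature-ranking
  tests have a well-defined right answer. Because the construction uses
  realized (post-clipping) values, zero-noise configurations recover the
  planted raw slopes exactly by ordinary regression.
* **IL-6.** Fasting ≈ 0.48 ± 0.28 units with rises of ~0.45 (4 h) and
  0.81 ± 0.50 (6 h) drawn independently of every meal-response quantity —
  postprandial IL-6 is simulated as meal-independent (consistent with a
  cannulation-driven rise), yielding ~94–95% risers. IL-6 units are treated as
  opaque "marker units" throughout.
* **Covariates.** Age U(18, 65), 72% female, BMI N(25.6, 5.0) kg/m²,
  VFM N(1.0, 0.35) arbitrary mass units, ten mutually independent microbiome
  PCs with geometrically decaying SDs. Sex enters only as small level shifts
  (women higher IL-6, men higher GlycA) plus an optional planted sex-specific
  rise for interaction-test power studies. Covariates are otherwise mutually
  independent; the only planted dependence is the VFM → TG path, keeping every
  test's target identifiable.

What the generator does *not* emulate: assay-specific error structure, twin
relatedness, diet composition effects, circadian drift, or any nonlinearity —
all couplings are linear on standardized scales. Tests passing on this cohort
show the estimators recover planted linear effects at realistic noise levels;
they do not certify behavior under model misspecification.

## GWAS summary-statistics generators

Per SNP: EAF ~ U(0.05, 0.95); true instrument effect γ_j ~ N(0.08, 0.02);
estimate SEs follow 1/sqrt(2p(1−p)n) (per-allele effects on standardized
traits), with n_exposure = 300k and n_outcome = 100k by default, giving mean
F ≈ 700 (strong instruments). Outcome effects are β·γ_j + pleiotropy_j, with
optional directional/balanced pleiotropy and designated outlier SNPs. The
three-trait variant plants an exposure → mediator → outcome chain (defaults
α = 0.13, β = 0.49, direct effect chosen so the total is 0.22) with separate
exposure- and mediator-instrument panels over one shared SNP set; mediator
instruments have zero effect on the exposure, making the reverse edge null by
construction. All draws flow from per-block child generators of one seed.

## Estimators

* **IVW**: β̂ = Σw_j β̂_j / Σw_j with w_j = γ̂_j²/σ_Γj² (equivalently weighted
  regression through the origin); fixed SE (Σw_j)^−1/2, multiplicative
  random-effects SE inflated by max(1, sqrt(Q/(J−1))).
* **MR-Egger**: weighted regression with intercept after orienting all γ̂_j ≥ 0;
  SEs scaled by max(1, sqrt(Q′/(J−2))), t-tests on J−2 df; the intercept is the
  directional-pleiotropy test. With the intercept forced to zero it reduces
  exactly to fixed-effect IVW.
* **MR-PRESSO**: observed RSS of leave-one-out IVW residuals compared with its
  parametric null distribution (Γ*_j ~ N(β̂_{(−j)}γ̂_j, σ_Γj), default 1000
  simulations); per-SNP outlier p-values from the analogous per-SNP comparison
  with Bonferroni adjustment. The outlier search runs only when the global test
  is significant, as in the originating method; note the per-SNP empirical
  p-value has a floor of J/(n_sim+1), so n_sim must exceed J/α for flags to be
  possible. The distortion test compares the outlier-removal shift against
  removing random same-size SNP subsets (1000 draws).
* **MR-RAPS**: solves Σψ(t_j) ∂t_j/∂β = 0 with
  t_j = (Γ̂_j − βγ̂_j)/sqrt(σ_Γj² + β²σ_γj² + τ²); ψ identity or Huber
  (k = 1.345). τ², when enabled, solves Σ(ψ(t_j)² − δ) = 0 floored at zero
  (δ = E[ψ(Z)²] under N(0,1)); β and τ² are alternated to convergence and the
  SE is a sandwich estimate. In the no-exposure-noise limit the estimating
  equation reduces to the IVW normal equations.
* **Mediation**: indirect = α·β exactly; proportion = α·β/γ (undefined when
  γ = 0, flagged); SE by the first-order delta method
  sqrt(β²se_α² + α²se_β²). The proportion is reported both as a fraction and
  as a truncated integer percent.

## Path analysis

Manifest variables only; recursive (acyclic) models with independent
endogenous residuals and a free covariance block among exogenous nodes.
Estimation minimizes the ML discrepancy on the sample covariance
(complete-case rows; no FIML). Parametrization keeps variances positive (log
residual variances; Cholesky with log-diagonal for the exogenous block);
optimization is BFGS from a fixed deterministic start (zero coefficients,
sample variances/covariances) with gradient tolerance 1e-10 and a Nelder–Mead
polish if the quasi-Newton stalls — no randomness anywhere. χ² = (n−1)F at the
optimum; SEs from the inverse numerical Hessian of F scaled by 2/(n−1);
standardized β = estimate × sd(source)/sd(target) with sample SDs. CFI/TLI use
the independence baseline (all covariances zero); TLI above 1 is capped with
the raw value retained; TLI/RMSEA are reported as not-applicable for saturated
models (df = 0) or a degenerate baseline (χ²_b/df_b = 1). Fit indices are
reported without verdicts. Covariate selection for the model feeds the top-k
random-forest-ranked features, optionally filtering out postprandial curve
features to keep the fasting-state model identifiable.

## Prediction stage

Random forest: 500 trees, p/3 features per split, 5-fold CV, all seeds
explicit. Q² = 1 − PRESS/TSS with PRESS the held-out squared error and TSS
taken about each training fold's mean, so the reference prediction never sees
held-out data; negative Q² is reported as-is. The outcome dichotomization
"top 30%" uses the 70th linear-interpolation percentile with labels strictly
above the cutoff. AUC uses midranks (exact under ties); the CI is DeLong's
(deterministic), checked against an independent reference implementation.

## Reporting conventions

Percent values carry two conventions used side by side in the cohort
literature this package targets: integer percents round to nearest
(168.75 → 169), one-decimal percents truncate toward zero (42.769 → 42.7).
`format_percent` implements both; full-precision values are always retained
alongside.

## Numerical and design choices

* "Rising" responder status is strict ((6 h − 0 h) > ε with ε = 0 by default,
  configurable), so riser/decliner/unchanged fractions always sum to one.
* Levene's test defaults to the mean-centered (classic) statistic;
  median-centering (Brown–Forsythe) is a parameter.
* Age dichotomizes at the cohort median for interaction tests.
* Correlation tables use raw GlycA and ln(IL-6 + 1).
* Harmonization drops strand-ambiguous palindromic SNPs with EAF in
  [0.42, 0.58] (configurable window) and SNPs whose allele pairs neither match
  nor swap; every action is logged.
* Instruments are assumed independent (no LD clumping); the generators
  guarantee it.
* The curve functional form (Gaussian bumps on a baseline) is chosen for
  smoothness and closed-form feature arithmetic, not as a physiological model.

## Problem sizes

The test suite exercises recovery at the scales where the statistical claims
are sharp but cheap: IVW bias/coverage at J = 50 over 500 replicates; Egger
intercept recovery over 500 replicates; PRESSO size over 100 and power over 60
replicates at 1000 simulations each; path-model slope recovery at n = 10⁵ and
fit-index behavior over 100 refits at n = 1000; Levene size over 2000
replicates; network-MR recovery over 200 replicates; cohort-level checks at
n = 300–1000 participants. The acceptance script uses the same operating
points with replicate counts trimmed (e.g. 200 for IVW, 100 for network MR) to
keep a full run in the tens of seconds.

## Known limitations

* The MR estimators assume uncorrelated instruments and two-sample
  independence; neither is checked from data.
* MR-PRESSO's distortion test uses subset-removal resampling rather than the
  exact bootstrap of the original software; p-values are empirical with a
  1/(n_perm+1) floor.
* The path-model fitter handles manifest variables only — no latent factors,
  no missing-data likelihood, no categorical estimators, no modification
  indices.
* DeLong CIs are clipped to [0, 1] rather than logit-transformed, so they can
  touch the boundary for near-perfect discrimination.
* The synthetic cohort's realized-feature construction means planted
  standardized slopes for *postprandial* couplings are exact only up to the
  truncation of negative amplitudes and the positivity clipping, both rare at
  the default operating point.
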