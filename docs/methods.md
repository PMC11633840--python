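# Methods

## Model

`mllca` implements the nonparametric multilevel latent class (LC) model
with covariates for binary items. Lower-level units i = 1..n_j (e.g.
students) are nested in groups j = 1..J (e.g. schools). Each unit carries
H binary responses Y_ijh, a lower-level latent class X_ij ∈ {1..T}, and
each group a discrete higher-level class W_j ∈ {1..M} acting as a
nonparametric random effect. The probability structure is

    P(Y_ij | Z_ij) = Σ_m P(W_j=m | Z^H_j) Σ_t P(X_ij=t | W_j=m, Z_ij)
                     Π_h φ_th^{Y_ijh} (1−φ_th)^{1−Y_ijh},

with multinomial-logit parametrizations

    P(W_j=m | Z^H_j)        ∝ exp(α_0m + α_1m Z^H_j),
    P(X_ij=t | W_j=m, Z_ij) ∝ exp(γ_0tm + γ_1tm Z^L_ij + γ_2tm Z^H_j),
    P(Y_ijh=1 | X_ij=t)     = logistic(β_th).

Assumptions: local independence of items given X; X_ij conditionally
independent across units given W_j; item probabilities do not depend on
W or Z directly; responses independent of covariates given (X, W). The
first class at each level and item response 0 are reference categories
with zero coefficients; the zero slices are stored explicitly and never
counted among free parameters.

One higher- and one lower-level covariate in the classical presentation
generalize here to p_H, p_L ≥ 0 covariates by vectorizing α_1m, γ_1tm,
γ_2tm. Covariates are not rescaled internally; standardizing continuous
covariates before fitting is recommended.

## Estimators

* **one_step** — joint ML of measurement and structural model (EM on the
  full model).
* **two_step** — stage 1 fits the multilevel measurement model (no
  covariates); stage 2 fixes φ and fits the structural model by ML.
* **three_step** — step 1 fits the *single-level* LC model ignoring the
  grouping; step 2 classifies units (modal / proportional / random rule)
  and estimates the classification-error matrix
  D[s,t] = P(assigned s | true t) from the posteriors, weighting response
  patterns by their empirical frequency; step 3 fits the multilevel
  structural model treating the assignment as a single error-prone
  indicator with D held fixed. Conditioning on D reproduces the
  attenuation-free estimate: ignoring the classification error
  (`correction=False`) shrinks covariate effects toward zero.

The EM engine is shared: a "measurement kernel" supplies
log P(indicator block of unit i | X_ij=t), realized either by the item
product (free or fixed φ) or by log D[assigned_i, t] with D constant (for
soft assignments, Σ_s w_is log D[s,t]). The E-step is exact: given W the
within-group structure factorizes, so posteriors of W and of X given W
have closed forms. The M-step uses closed forms for φ and for
covariate-free class probabilities, and a small warm-started Newton solver
for the weighted multinomial-logit subproblems (a few line-searched steps
per EM iteration; a generalized EM that keeps the observed log-likelihood
non-decreasing — asserted to 1e−8 per iteration in debug mode).

### Numerical choices

* All likelihoods accumulate in log space; per-group terms are sums of
  per-unit log-sum-exp values, never probability-space products.
* Probabilities are clipped to [1e−10, 1−1e−10] before logging (EM can
  touch the boundary under perfect separation).
* D is clipped entrywise to [1e−6, 1] and columns renormalized before
  step 3; exact zeros are common under near-perfect separation and would
  produce −∞ terms.
* Modal-assignment ties break toward the lowest class index.
* Multistart policy: responsibilities (single-level) or coefficient draws
  (multilevel) initialize `n_starts` random starts (default 20 for item
  kernels, 5 for the far smoother fixed-D kernel); every start runs
  `short_iters` (default 40) EM iterations, the best `n_refine` (default
  3) continue to convergence, and the best final log-likelihood wins.
  Convergence: relative log-likelihood change < 1e−8, at most 1000
  iterations. All starts are seeded; the random assignment rule consumes
  a stream derived from the fit seed, isolated from data generation.
* Label switching: item-kernel fits sort lower classes by decreasing mean
  φ (ties by the first item) so "class 1 = all-high"; in simulations,
  classes are greedily matched to the generating profile by mean |Δφ|
  (lower level) and by L1 distance between conditional class proportions
  at z = 0 (higher level). Fixed-D fits need no lower-level alignment —
  the asymmetric D anchors the labels.
* Standard errors: observed information — the central-difference Hessian
  (step 1e−5·max(1,|θ|)) of the fitted log-likelihood over the free
  parameters, inverted. One-step SEs can include the measurement logits
  (`which="all"`); two-step SEs come from the stage-2 Hessian *without*
  a correction for stage-1 uncertainty and therefore tend to be
  conservative; three-step SEs condition on D as known and are slightly
  optimistic. Both properties are inherent to the estimators as defined
  and are reproduced, not corrected, here.

## Model selection

BIC uses −2ℓ + k·log(n) with n = N (units) when comparing T and n = J
(groups) when comparing M at fixed T — the higher-level mixture has only
J independent realizations. Sequential selection picks T with M=1, then M
at that T, then re-picks T; simultaneous selection scans the full (T, M)
grid (BIC with n = N). The entropy R²,
1 − mean posterior entropy / marginal entropy, is reported at both
levels. The package default computes it from the fitted covariate-free
multilevel measurement model — the diagnostic a practitioner sees in LC
software output; `r2_from_params` computes it under any supplied
parameters instead (e.g. generating values), using the full-information
posteriors P(X_ij | Y_j, Z) and P(W_j | Y_j, Z). The two conventions
differ mainly at the higher level in weakly separated designs, where the
full-information posterior is sharper than the fitted measurement-only
one.

## Synthetic-data generator

`build_population` instantiates the standard study design: T=3, M=2,
H=10, ω=(0.6, 0.4), one standard-normal lower-level covariate, block item
profiles (class 1 high on all items, class 2 on the last five, class 3 on
none) with most-likely response probability s ∈ {0.7, 0.8, 0.9} (small /
moderate / large lower-level separation), and random intercepts anchored
so the conditional class proportions at z=0 are (0.29,0.33,0.38) /
(0.38,0.33,0.29) (moderate higher-level separation) or (0.14,0.32,0.54) /
(0.60,0.25,0.15) (large). Slopes are γ_121=γ_131=−0.25,
γ_122=γ_132=+0.25, or all zero in the null arm. Anchoring at z=0 rather
than marginally over z shifts the implied marginal proportions only in
the third decimal at these slopes. Group classes are drawn i.i.d. from ω
(group counts are not fixed), and group sizes are equal at n_j ∈
{100, 500} with J ∈ {30, 50, 100}.

What the generator does *not* emulate: unequal group sizes, item
missingness, ordinal items, direct covariate effects on items
(measurement non-invariance), or within-group covariate correlation.
Passing simulation-based tests therefore demonstrates estimator
correctness under a correctly specified model, not robustness to those
violations.

`run_study` runs the Monte Carlo comparison: per replication it
simulates a dataset, fits the requested estimators on identical data,
aligns labels to the population, and records the four slope estimates and
(optionally) their SEs; it aggregates relative absolute bias |mean−θ|/|θ|
(absolute bias in the zero-slope arm), Monte Carlo SD, mean SE, SE/SD
ratio, 95% Wald coverage and rejection rates, averaged over the four
slopes, with failed replications excluded and counted. A master seed
spawns independent per-replication streams, so results are exactly
reproducible.

## Problem sizes used in the shipped checks

The reference study uses 500 replications per condition; the test suite
and the acceptance script run scaled-down versions chosen as the package's
own default problem sizes: 200 replications for the SE-quality study in
the large/large condition (n_j=100, J=30), 100 replications for the bias
orderings and for slope recovery (recovery at n_j=150, J=30), 100
datasets per separation level for entropy-R² summaries (25–34 per design
cell, mixing the cells that share the level, as the reference quantities
average over them). At these scales the Monte Carlo error of the reported
averages is roughly 0.01–0.02 for R² values and about one percentage
point for bias and SE ratios.

## Known limitations

* The pseudo-ML variance correction for two-step SEs (step-1 uncertainty
  propagation) is not implemented; two-step SEs are reported with a
  documented caveat.
* Parametric (continuous) higher-level random effects, polytomous items,
  missing data, and measurement non-invariance corrections are out of
  scope.
* The fixed-D third step inherits the well-known sensitivity of
  three-step estimation to weak lower-level separation: with small
  separation its bias exceeds the one-step bias — a property of the
  method, reproduced by the tests, not a defect of the implementation.
* Greedy label matching can in principle differ from the optimal
  assignment on severely degenerate fits; with T=3, M=2 and the block
  profiles used here it coincides.
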