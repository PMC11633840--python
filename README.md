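# mllca — multilevel latent class analysis with covariates

`mllca` estimates nonparametric multilevel latent class (LC) models for
binary items: lower-level units (students, patients, respondents) nested
in groups (schools, centres, countries), with a discrete latent class
X_ij ∈ {1..T} per unit, a discrete higher-level class W_j ∈ {1..M} per
group acting as a nonparametric random effect, and covariates predicting
class membership at both levels,

    P(Y_ij | Z_ij) = Σ_m P(W_j=m | Z^H_j) Σ_t P(X_ij=t | W_j=m, Z_ij)
                     Π_h φ_th^{Y_ijh} (1−φ_th)^{1−Y_ijh},

with multinomial-logit structural models for P(W|Z^H) and P(X|W,Z).
It is aimed at applied researchers who want stepwise workflows — build
the classification first, add covariates later — without the attenuation
bias that classification error otherwise causes.

Three estimators share one EM engine:

* **one-step** — joint ML of measurement and structural model;
* **two-step** — measurement model first, structural model with φ fixed;
* **bias-adjusted three-step** — fit a single-level LC model, assign
  units to classes (modal / proportional / random), estimate the
  classification-error matrix D[s,t] = P(assigned s | true t), then fit
  the multilevel structural model treating the assignment as a single
  error-prone indicator with D fixed. Setting `correction=False` gives
  the naive third step, which shrinks covariate effects toward zero.

Also included: BIC-based sequential/simultaneous selection of (T, M),
entropy-based R² separation diagnostics at both levels, observed-
information standard errors, a synthetic-data generator for the standard
two-level study design, and a Monte Carlo module comparing the
estimators' bias, efficiency, SE quality, and coverage.

## Worked example

Simulate one dataset from the large-separation design (T=3 classes,
M=2 group classes, 10 items, 30 groups of 100 units, one standard-normal
covariate z with slopes ±0.25) and run the bias-adjusted three-step
estimator:

```python
import numpy as np
from mllca import (FitConfig, build_population, simulate_dataset, three_step,
                   standard_errors, align_to_population, extract_slopes)
from mllca.estimators import slope_indices

pop = build_population("large", "large")
data, w, x = simulate_dataset(pop, n_j=100, J=30, seed=7)

fit = three_step(data, T=3, M=2, rule="modal", config=FitConfig(seed=7))
fit.params = align_to_population(fit.params, pop, align_lower=False)
fit = standard_errors(fit, data, fit.meta["_kernel"])

print("log-likelihood:", round(fit.loglik, 2))
print("D diagonal:", np.round(np.diag(np.array(fit.meta["d_matrix"])), 3))
idx = slope_indices(fit.params.structural)
for name, est, se in zip(["gamma[1,2,z]", "gamma[1,3,z]", "gamma[2,2,z]", "gamma[2,3,z]"],
                         extract_slopes(fit.params), np.asarray(fit.se)[idx]):
    print(f"{name}: {est:+.3f} (SE {se:.3f})")
```

Output:

```
log-likelihood: -2919.87
D diagonal: [0.99  0.979 0.99 ]
gamma[1,2,z]: -0.238 (SE 0.075)
gamma[1,3,z]: -0.219 (SE 0.070)
gamma[2,2,z]: +0.298 (SE 0.073)
gamma[2,3,z]: +0.291 (SE 0.087)
```

The D diagonal near 0.98–0.99 says step-2 classification is almost
error-free at this separation; the four covariate slopes (class 2 and 3
vs class 1, within each group class) recover the generating values
−0.25, −0.25, +0.25, +0.25 well within one standard error.

A command-line interface mirrors the library: `mllca fit`, `mllca
select`, `mllca study`, `mllca fixture` (see `mllca --help`). Input is a
delimited table with a `group` column, binary `item*` columns, and
optional covariate columns.

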