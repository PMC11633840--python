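"""One-step, two-step, and bias-adjusted three-step estimators.

* one_step: measurement and structural model fitted jointly by ML.
* two_step: the multilevel measurement model (no covariates) is fitted
  first; the structural model is then fitted with phi held fixed.
* three_step: a single-level measurement model is fitted ignoring the
  grouping; units are classified; the structural multilevel model is then
  fitted treating the assignment as one error-prone indicator with the
  classification-error matrix D held fixed, which removes the attenuation
  bias of the naive third step.

Standard errors come from the observed information (numerical Hessian of
the fitted log-likelihood over the free parameters).  Two-step SEs ignore
step-1 uncertainty and tend to be conservative relative to pseudo-ML
corrected ones; three-step SEs condition on D as known and are therefore
slightly optimistic — both caveats are inherent to the estimators as
implemented, not defects of the optimizer.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .classify import assign, clip_error_matrix, error_matrix, posterior_probs
from .data import ItemResponseData
from .engine import FixedDKernel, ItemKernel, ml_em_fit, ml_loglik
from .params import (
    MeasurementParams,
    ModelParams,
    pack_structural,
    unpack_structural,
)
from .numdiff import hessian
from .results import FitConfig, FitResult, SingularInformationError
from .single_level import sl_em_fit


def one_step(data: ItemResponseData, T: int, M: int, config: FitConfig | None = None) -> FitResult:
    """Joint ML fit of the full multilevel LC model with covariates."""
    config = config or FitConfig()
    fit = ml_em_fit(data, T, M, ItemKernel(), config=config)
    fit.meta["estimator"] = "one_step"
    return fit


def two_step(data: ItemResponseData, T: int, M: int, config: FitConfig | None = None) -> FitResult:
    """Measurement model first (multilevel, no covariates), structure second."""
    config = config or FitConfig()
    stage1_data = ItemResponseData(items=data.items, group_id=data.group_index)
    stage1 = ml_em_fit(stage1_data, T, M, ItemKernel(), config=config)
    phi = stage1.params.measurement.phi
    stage2 = ml_em_fit(
        data, T, M, ItemKernel(fixed_phi=phi),
        config=replace(config, seed=config.seed + 1),
    )
    stage2.meta["estimator"] = "two_step"
    stage2.meta["stage1_loglik"] = stage1.loglik
    stage2.meta["stage1_bic"] = stage1.bic
    return stage2


def three_step(
    data: ItemResponseData,
    T: int,
    M: int,
    rule: str = "modal",
    config: FitConfig | None = None,
    correction: bool = True,
    phi_ref: np.ndarray | None = None,
    step1_fit: FitResult | None = None,
) -> FitResult:
    """Bias-adjusted three-step ML estimation.

    `correction=False` gives the naive third step (D replaced by the
    identity), which attenuates covariate effects toward zero.  `phi_ref`
    optionally re-anchors the step-1 class labels to a reference item
    profile before classification (used in simulations so that class k
    means the same thing in every replication).  A precomputed `step1_fit`
    can be supplied to share stage-1 work across variants.
    """
    config = config or FitConfig()
    step1 = step1_fit or sl_em_fit(data, T, config=config)
    params1 = step1.params
    if phi_ref is not None:
        params1 = _align_single_level(params1, np.asarray(phi_ref))

    post = posterior_probs(params1, data)
    w = assign(post, rule=rule, seed=config.seed + 7919)
    cem = clip_error_matrix(error_matrix(post, w))
    d_used = np.eye(T) if not correction else cem.d
    if not correction:
        d_used = np.clip(d_used, 1e-6, 1.0)
        d_used /= d_used.sum(axis=0, keepdims=True)
    kernel = FixedDKernel(d_used, w.w)

    step3_cfg = replace(config, n_starts=min(config.n_starts, 5),
                        seed=config.seed + 2)
    fit = ml_em_fit(data, T, M, kernel, config=step3_cfg)
    fit.meta["estimator"] = "three_step" if correction else "three_step_naive"
    fit.meta["rule"] = rule
    fit.meta["step1_loglik"] = step1.loglik
    fit.meta["d_matrix"] = cem.d.tolist()
    fit.meta["d_marginal"] = cem.marginal.tolist()
    fit.meta["_kernel"] = kernel  # for SE computation; not serialized
    return fit


def _align_single_level(params, phi_ref: np.ndarray):
    """Greedy class matching to a reference profile by mean |phi - ref|."""
    from .params import SingleLevelParams

    T = params.measurement.n_classes
    cost = np.abs(params.measurement.phi[:, None, :] - phi_ref[None, :, :]).mean(axis=2)
    perm = -np.ones(T, dtype=int)  # perm[new] = old
    free_rows, free_cols = set(range(T)), set(range(T))
    for _ in range(T):
        best = min(
            ((cost[r, c], r, c) for r in free_rows for c in free_cols)
        )
        _, r, c = best
        perm[c] = r
        free_rows.discard(r)
        free_cols.discard(c)
    return SingleLevelParams(
        params.class_props[perm], MeasurementParams(params.measurement.phi[perm])
    )


def standard_errors(
    fit: FitResult, data: ItemResponseData, kernel, which: str = "structural"
) -> FitResult:
    """Observed-information SEs at the fitted estimate.

    The covariance is the inverse negative Hessian of the log-likelihood
    over the free parameters (structural only by default; with
    which="all" and a free item kernel, the measurement logits are
    included).  Raises SingularInformationError with eigen-diagnostics if
    the information matrix is not positive definite.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    params: ModelParams = fit.params
    theta0 = pack_structural(params.structural)
    include_meas = (
        which == "all"
        and isinstance(kernel, ItemKernel)
        and kernel.fixed_phi is None
    )
    if include_meas:
        beta0 = params.measurement.beta.ravel()
        theta0 = np.concatenate([theta0, beta0])
        n_struct = theta0.size - beta0.size

    def ll(theta):
        if include_meas:
            structural = unpack_structural(theta[:n_struct], params.structural)
            phi = 1.0 / (1.0 + np.exp(-theta[n_struct:].reshape(params.measurement.phi.shape)))
            p = ModelParams(MeasurementParams(phi), structural)
        else:
            structural = unpack_structural(theta, params.structural)
            p = ModelParams(params.measurement, structural)
        return ml_loglik(p, data, kernel)

    H = hessian(ll, theta0)
    info = -(H + H.T) / 2.0
    eigvals = np.linalg.eigvalsh(info)
    if eigvals.min() <= 0:
        raise SingularInformationError(
            "observed information is not positive definite", eigenvalues=eigvals
        )
    vcov = np.linalg.inv(info)
    fit.vcov = vcov
    fit.se = np.sqrt(np.diag(vcov))
    if include_meas:
        fit.free_names = list(fit.free_names) + [
            f"beta[{t+1},{h+1}]"
            for t in range(params.measurement.n_classes)
            for h in range(params.measurement.n_items)
        ]
    return fit


def slope_indices(structural, covariate: int = 0) -> list[int]:
    """Indices of the lower-level covariate slopes gamma[m, t, 1+covariate]
    within the packed free-parameter vector (all m, all non-reference t)."""
    M, T = structural.n_high, structural.n_low
    ca, cg = structural.alpha.shape[1], structural.gamma.shape[2]
    base = (M - 1) * ca
    idx = []
    for m in range(M):
        for t in range(T - 1):
            idx.append(base + (m * (T - 1) + t) * cg + 1 + covariate)
    return idx
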