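"""EM engine for the multilevel latent class model over a measurement kernel.

The model couples a discrete higher-level class W_j (a nonparametric group
random effect) with lower-level classes X_ij:

    P(Y_j | Z_j) = sum_m P(W_j=m | Z^H_j) prod_i sum_t P(X_ij=t | W_j=m, Z_ij) K(i, t),

where the kernel K(i, t) is the probability of unit i's observed indicator
block given X_ij = t.  Two kernels realize this contract:

* ItemKernel -- K is the local-independence product over H binary items
  with free response probabilities phi (the one-step / two-step models);
* FixedDKernel -- the step-2 class assignment is the single indicator and
  K(i, t) = P(assigned_i | X=t) with the classification-error matrix D held
  fixed (the corrected third step).  It contributes no free parameters.

Everything is accumulated in log space; the product over units within a
group is a sum of per-unit log-sum-exp terms, never a probability-space
product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import ItemResponseData
from .mnlogit import fit_weighted_mnlogit
from .params import (
    EPS,
    MeasurementParams,
    ModelParams,
    StructuralParams,
    class_probs_high_all,
    class_probs_low_all,
    item_logprob_matrix,
    n_free_structural,
)
from .results import ConvergenceError, FitConfig, FitResult


class ItemKernel:
    """Local-independence Bernoulli item block with free (or fixed) phi."""

    def __init__(self, fixed_phi: np.ndarray | None = None):
        self.fixed_phi = None if fixed_phi is None else np.asarray(fixed_phi, float)

    def logk(self, measurement: MeasurementParams, data: ItemResponseData) -> np.ndarray:
        return item_logprob_matrix(measurement, data.items)

    def n_free(self, T: int, H: int) -> int:
        return 0 if self.fixed_phi is not None else T * H

    def update(self, measurement, q, data) -> MeasurementParams:
        if self.fixed_phi is not None:
            return measurement
        phi = (q.T @ data.items) / np.clip(q.sum(axis=0)[:, None], EPS, None)
        return MeasurementParams(phi)


class FixedDKernel:
    """Step-2 assignment as a single indicator with known error matrix D.

    log K(i, t) = sum_s w[i, s] log d[s, t]; for hard assignments the sum
    collapses to log d[assigned_i, t].
    """

    def __init__(self, d: np.ndarray, w: np.ndarray):
        self.d = np.asarray(d, dtype=float)
        self.w = np.asarray(w, dtype=float)
        if (self.d <= 0).any():
            raise ValueError("D must be strictly positive (clip before use)")
        self._logk = self.w @ np.log(self.d)

    def logk(self, measurement, data) -> np.ndarray:
        return self._logk

    def n_free(self, T: int, H: int) -> int:
        return 0

    def update(self, measurement, q, data) -> MeasurementParams:
        return measurement


@dataclass
class GroupPosteriors:
    """pw[j, m] = P(W_j=m | data_j); pxw[i, m, t] = P(X_ij=t | W_j=m, data)."""

    pw: np.ndarray
    pxw: np.ndarray
    loglik: float


def _structural_logs(params: ModelParams, data: ItemResponseData):
    zh = data.z_high if data.z_high is not None else np.empty((data.n_groups, 0))
    om = class_probs_high_all(params.structural, zh)  # (J, M)
    px = class_probs_low_all(params.structural, data.z_low_matrix(), data.z_high_per_unit())
    return np.log(np.clip(om, EPS, None)), np.log(np.clip(px, EPS, None))


def e_step(params: ModelParams, data: ItemResponseData, kernel) -> GroupPosteriors:
    """Exact posteriors for both latent levels (closed form given W)."""
    log_om, log_px = _structural_logs(params, data)  # (J,M), (N,M,T)
    logk = kernel.logk(params.measurement, data)  # (N, T)
    a = log_px + logk[:, None, :]  # (N, M, T)
    li = logsumexp(a, axis=2)  # (N, M): log P(block_i | W=m)
    pxw = np.exp(a - li[:, :, None])
    lg = data.group_reduce(li)  # (J, M)
    lw = log_om + lg
    lj = logsumexp(lw, axis=1)
    pw = np.exp(lw - lj[:, None])
    return GroupPosteriors(pw=pw, pxw=pxw, loglik=float(lj.sum()))


def ml_loglik(params: ModelParams, data: ItemResponseData, kernel) -> float:
    """Multilevel log-likelihood (items kernel: full model; D kernel: step 3)."""
    if data.n_groups == 0:
        raise ValueError("no groups in data")
    log_om, log_px = _structural_logs(params, data)
    logk = kernel.logk(params.measurement, data)
    li = logsumexp(log_px + logk[:, None, :], axis=2)
    lw = log_om + data.group_reduce(li)
    return float(logsumexp(lw, axis=1).sum())


# ----------------------------------------------------------------------
# M-step
# ----------------------------------------------------------------------

def _m_step_structural(
    structural: StructuralParams, data: ItemResponseData, post: GroupPosteriors
) -> StructuralParams:
    M, T = structural.n_high, structural.n_low
    alpha = structural.alpha.copy()
    gamma = structural.gamma.copy()

    if M > 1:
        if data.p_high == 0:
            om = np.clip(post.pw.mean(axis=0), EPS, None)
            om /= om.sum()
            alpha[:, 0] = np.log(om / om[0])
        else:
            Xd = np.column_stack([np.ones(data.n_groups), data.z_high])
            # a few warm-started Newton steps per EM iteration (GEM: each
            # line-searched step increases the expected complete-data ll)
            alpha = fit_weighted_mnlogit(Xd, post.pw, B0=alpha, max_iter=3)

    if T > 1:
        pw_units = np.repeat(post.pw, data.group_sizes, axis=0)  # (N, M)
        if data.p_low == 0 and data.p_high == 0:
            for m in range(M):
                q = pw_units[:, m, None] * post.pxw[:, m, :]
                pi = np.clip(q.sum(axis=0), EPS, None)
                pi /= pi.sum()
                gamma[m, :, 0] = np.log(pi / pi[0])
        else:
            Xd = np.column_stack(
                [np.ones(data.n_units), data.z_low_matrix(), data.z_high_per_unit()]
            )
            for m in range(M):
                W = pw_units[:, m, None] * post.pxw[:, m, :]
                gamma[m] = fit_weighted_mnlogit(Xd, W, B0=gamma[m], max_iter=3)

    return StructuralParams(alpha=alpha, gamma=gamma)


def _run_em(params, data, kernel, max_iter, tol, check_monotone):
    ll_prev = -np.inf
    path = []
    for it in range(max_iter):
        post = e_step(params, data, kernel)
        path.append(post.loglik)
        if check_monotone and post.loglik < ll_prev - 1e-8 * (1.0 + abs(ll_prev)):
            raise AssertionError(
                f"EM log-likelihood decreased: {ll_prev} -> {post.loglik}"
            )
        if np.isfinite(ll_prev) and (post.loglik - ll_prev) < tol * (1.0 + abs(post.loglik)):
            return params, post.loglik, it + 1, True, path
        structural = _m_step_structural(params.structural, data, post)
        q = np.einsum("nm,nmt->nt", np.repeat(post.pw, data.group_sizes, axis=0), post.pxw)
        measurement = kernel.update(params.measurement, q, data)
        params = ModelParams(measurement=measurement, structural=structural)
        ll_prev = post.loglik
    post = e_step(params, data, kernel)
    path.append(post.loglik)
    return params, post.loglik, max_iter, False, path


def _random_start(data, T, M, kernel, rng) -> ModelParams:
    if isinstance(kernel, ItemKernel) and kernel.fixed_phi is None:
        resp = rng.dirichlet(np.ones(T), size=data.n_units)
        phi = (resp.T @ data.items) / resp.sum(axis=0)[:, None]
        measurement = MeasurementParams(phi)
    elif isinstance(kernel, ItemKernel):
        measurement = MeasurementParams(kernel.fixed_phi)
    else:
        measurement = MeasurementParams(np.full((T, max(data.n_items, 1)), 0.5))
    alpha = np.zeros((M, 1 + data.p_high))
    gamma = np.zeros((M, T, 1 + data.p_low + data.p_high))
    alpha[1:] = rng.normal(0.0, 0.3, size=alpha[1:].shape)
    gamma[:, 1:, :] = rng.normal(0.0, 0.3, size=gamma[:, 1:, :].shape)
    return ModelParams(measurement=measurement, structural=StructuralParams(alpha, gamma))


def _sort_lower_classes(params: ModelParams) -> ModelParams:
    """Deterministic lower-class labels: decreasing mean item probability."""
    phi = params.measurement.phi
    order = np.lexsort((-phi[:, 0], -phi.mean(axis=1)))
    return permute_params(params, perm_t=order)


def permute_params(
    params: ModelParams, perm_t=None, perm_m=None
) -> ModelParams:
    """Relabel classes; perm arrays map new index -> old index.

    Logistic coefficients are re-referenced by subtracting the new
    reference category's row, which leaves all class probabilities intact.
    """
    s = params.structural
    perm_t = np.arange(s.n_low) if perm_t is None else np.asarray(perm_t)
    perm_m = np.arange(s.n_high) if perm_m is None else np.asarray(perm_m)
    phi = params.measurement.phi[perm_t]
    gamma = s.gamma[perm_m][:, perm_t, :]
    gamma = gamma - gamma[:, [0], :]
    alpha = s.alpha[perm_m]
    alpha = alpha - alpha[[0], :]
    return ModelParams(
        measurement=MeasurementParams(phi),
        structural=StructuralParams(alpha=alpha, gamma=gamma),
    )


def ml_em_fit(
    data: ItemResponseData,
    T: int,
    M: int,
    kernel,
    config: FitConfig | None = None,
    init: ModelParams | None = None,
) -> FitResult:
    """Fit the multilevel LC model by multistart (generalized) EM.

    The M-step maximizes the expected complete-data log-likelihood exactly:
    closed forms for phi and for covariate-free class probabilities, and a
    Newton solve of the weighted multinomial logit for covariate models, so
    the observed log-likelihood is non-decreasing across iterations.
    """
    config = config or FitConfig()
    if T < 1 or M < 1:
        raise ValueError("T and M must be >= 1")
    rng = config.rng()

    shorts = []
    n_starts = config.n_starts if init is None else max(1, config.n_starts)
    for s in range(n_starts):
        params0 = init if (init is not None and s == 0) else _random_start(data, T, M, kernel, rng)
        out = _run_em(params0, data, kernel, config.short_iters, config.tol, config.check_monotone)
        shorts.append(out)
    shorts.sort(key=lambda r: -r[1])

    best = None
    for params0, ll0, it0, conv0, path0 in shorts[: config.n_refine]:
        if conv0:
            cand = (ll0, params0, it0, True, path0)
        else:
            params, ll, it, conv, path = _run_em(
                params0, data, kernel, config.max_iter, config.tol, config.check_monotone
            )
            cand = (ll, params, it0 + it, conv, path0 + path)
        if best is None or cand[0] > best[0]:
            best = cand

    ll, params, n_iter, converged, path = best
    if not converged:
        raise ConvergenceError(
            "multilevel EM did not converge in any refined start",
            best=FitResult(params, ll, False, n_iter, 0),
        )
    if isinstance(kernel, ItemKernel) and kernel.fixed_phi is None and T > 1:
        params = _sort_lower_classes(params)

    n_params = n_free_structural(params.structural) + kernel.n_free(T, data.n_items)
    names = _free_names(params.structural)
    return FitResult(
        params, ll, converged, n_iter, n_params,
        bic=-2 * ll + n_params * np.log(data.n_units),
        free_names=names,
        meta={"T": T, "M": M, "kernel": type(kernel).__name__,
              "seed": config.seed, "loglik_path": path},
    )


def _free_names(s: StructuralParams) -> list[str]:
    names = [
        f"alpha[{m+1},{c}]" for m in range(1, s.n_high) for c in range(s.alpha.shape[1])
    ]
    names += [
        f"gamma[{m+1},{t+1},{c}]"
        for m in range(s.n_high)
        for t in range(1, s.n_low)
        for c in range(s.gamma.shape[2])
    ]
    return names
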