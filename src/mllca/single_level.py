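"""Step-1 estimation: the simple latent class model, ignoring grouping.

The model is a T-component mixture of independent Bernoulli items,

    P(Y_i) = sum_t P(X=t) prod_h phi_th^{y_ih} (1 - phi_th)^{1 - y_ih},

fitted by EM with closed-form M-steps.  The multilevel structure and any
covariates are deliberately ignored here: this is the measurement-only
first step of the stepwise estimators.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .data import ItemResponseData
from .params import EPS, MeasurementParams, SingleLevelParams, item_logprob_matrix
from .results import ConvergenceError, FitConfig, FitResult


def sl_loglik(params: SingleLevelParams, data: ItemResponseData) -> float:
    """Log-likelihood of the simple LC model, log-sum-exp over classes."""
    if data.n_units == 0:
        raise ValueError("empty data")
    lp = np.log(params.class_props) + item_logprob_matrix(params.measurement, data.items)
    return float(logsumexp(lp, axis=1).sum())


def _responsibilities(params: SingleLevelParams, items: np.ndarray):
    lp = np.log(params.class_props) + item_logprob_matrix(params.measurement, items)
    li = logsumexp(lp, axis=1)
    return np.exp(lp - li[:, None]), float(li.sum())


def _m_step(resp: np.ndarray, items: np.ndarray) -> SingleLevelParams:
    props = resp.mean(axis=0)
    props = np.clip(props, EPS, None)
    props /= props.sum()
    phi = (resp.T @ items) / np.clip(resp.sum(axis=0)[:, None], EPS, None)
    return SingleLevelParams(props, MeasurementParams(phi))


def _run_em(params, items, max_iter, tol, check_monotone):
    ll_prev = -np.inf
    path = []
    for it in range(max_iter):
        resp, ll = _responsibilities(params, items)
        path.append(ll)
        if check_monotone and ll < ll_prev - 1e-8 * (1.0 + abs(ll_prev)):
            raise AssertionError(f"EM log-likelihood decreased: {ll_prev} -> {ll}")
        if np.isfinite(ll_prev) and (ll - ll_prev) < tol * (1.0 + abs(ll)):
            return params, ll, it + 1, True, path
        params = _m_step(resp, items)
        ll_prev = ll
    resp, ll = _responsibilities(params, items)
    path.append(ll)
    return params, ll, max_iter, False, path


def _align_by_phi_mean(params: SingleLevelParams) -> SingleLevelParams:
    """Relabel classes in decreasing order of mean item probability.

    Ties broken by the first item so that class 1 is the all-high profile.
    """
    phi = params.measurement.phi
    order = np.lexsort((-phi[:, 0], -phi.mean(axis=1)))
    return SingleLevelParams(
        params.class_props[order], MeasurementParams(phi[order])
    )


def sl_em_fit(data: ItemResponseData, T: int, config: FitConfig | None = None) -> FitResult:
    """Fit the simple LC model with T classes by multistart EM."""
    config = config or FitConfig()
    if T < 1:
        raise ValueError("T must be >= 1")
    if data.n_units < T:
        raise ValueError("need at least T units")
    items = data.items.astype(float)
    N, H = items.shape

    if T == 1:
        phi = items.mean(axis=0, keepdims=True)
        params = SingleLevelParams(np.ones(1), MeasurementParams(phi))
        ll = sl_loglik(params, data)
        n_params = H
        return FitResult(params, ll, True, 1, n_params,
                         bic=-2 * ll + n_params * np.log(N),
                         meta={"estimator": "single_level", "T": 1})

    rng = config.rng()
    # short runs from random responsibilities, refine the best few
    shorts = []
    for s in range(config.n_starts):
        resp0 = rng.dirichlet(np.ones(T), size=N)
        params = _m_step(resp0, items)
        params, ll, it, conv, path = _run_em(
            params, items, config.short_iters, config.tol, config.check_monotone
        )
        shorts.append((ll, conv, it, params, path))
    shorts.sort(key=lambda r: -r[0])

    best = None
    for ll0, conv0, it0, params0, path0 in shorts[: config.n_refine]:
        if conv0:
            cand = (ll0, params0, it0, True, path0)
        else:
            params, ll, it, conv, path = _run_em(
                params0, items, config.max_iter, config.tol, config.check_monotone
            )
            cand = (ll, params, it0 + it, conv, path0 + path)
        if best is None or cand[0] > best[0]:
            best = cand

    ll, params, n_iter, converged, path = best
    if not converged:
        raise ConvergenceError(
            "single-level EM did not converge in any refined start",
            best=FitResult(params, ll, False, n_iter, 0),
        )
    params = _align_by_phi_mean(params)
    n_params = (T - 1) + T * H
    return FitResult(
        params, ll, converged, n_iter, n_params,
        bic=-2 * ll + n_params * np.log(N),
        free_names=[f"p[{t+1}]" for t in range(1, T)]
        + [f"phi[{t+1},{h+1}]" for t in range(T) for h in range(H)],
        meta={"estimator": "single_level", "T": T, "seed": config.seed,
              "loglik_path": path},
    )
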