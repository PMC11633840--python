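"""Weighted multinomial logistic regression by Newton-Raphson.

This is the M-step workhorse of the EM algorithms: each observation carries
a vector of non-negative category weights (fractional responsibilities),
and the weighted log-likelihood

    l(B) = sum_i sum_k w_ik log P_ik(B),   P_i = softmax(X_i @ B.T)

is maximized over the coefficient rows B[1:], with B[0] fixed at zero for
identification.  The objective is concave, so Newton with step-halving
converges reliably; warm starts make repeated calls inside EM cheap.
"""

from __future__ import annotations

import numpy as np


def _loglik(X, W, B):
    logits = X @ B.T
    logits -= logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(logits).sum(axis=1))
    return float((W * logits).sum() - (W.sum(axis=1) * lse).sum())


def fit_weighted_mnlogit(
    X: np.ndarray,
    W: np.ndarray,
    B0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 1e-10,
) -> np.ndarray:
    """Return (K, p) coefficient matrix with row 0 identically zero.

    Parameters
    ----------
    X : (n, p) design matrix (include the intercept column explicitly).
    W : (n, K) non-negative category weights; rows need not sum to one.
    B0 : optional warm start, shape (K, p); row 0 is ignored.
    """
    n, p = X.shape
    K = W.shape[1]
    B = np.zeros((K, p)) if B0 is None else np.array(B0, dtype=float)
    B[0] = 0.0
    ll = _loglik(X, W, B)
    wi = W.sum(axis=1)
    for _ in range(max_iter):
        logits = X @ B.T
        logits -= logits.max(axis=1, keepdims=True)
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        # gradient over free rows 1..K-1
        G = X.T @ (W[:, 1:] - wi[:, None] * P[:, 1:])  # (p, K-1)
        g = G.T.ravel()  # order: (k, a)
        if np.max(np.abs(g)) < 1e-9:
            break
        # negative Hessian: block (k,l) = sum_i wi P_ik (d_kl - P_il) x x^T
        Pf = P[:, 1:]
        S = np.einsum("i,ik,il->ikl", wi, Pf, Pf)
        D = np.einsum("i,ik->ik", wi, Pf)
        S *= -1.0
        S[:, np.arange(K - 1), np.arange(K - 1)] += D
        H = np.einsum("ikl,ia,ib->kalb", S, X, X).reshape((K - 1) * p, (K - 1) * p)
        H[np.diag_indices_from(H)] += ridge
        try:
            step = np.linalg.solve(H, g).reshape(K - 1, p)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0].reshape(K - 1, p)
        scale = 1.0
        for _half in range(30):
            Bn = B.copy()
            Bn[1:] += scale * step
            lln = _loglik(X, W, Bn)
            if lln >= ll - 1e-12:
                break
            scale *= 0.5
        if lln < ll:  # no ascent found; keep current point
            break
        B, improved = Bn, lln - ll
        ll = lln
        if improved < tol * (1.0 + abs(ll)):
            break
    B[0] = 0.0
    return B
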