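"""Step-2: posterior classification and the classification-error matrix D.

Units are assigned to estimated classes from their step-1 posteriors by a
modal, proportional, or random rule; the resulting misclassification
probabilities d[s, t] = P(assigned = s | true = t) are estimated from the
posteriors themselves, weighting response patterns by their empirical
frequency.  D is column-stochastic: each column t sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import ItemResponseData
from .params import SingleLevelParams, item_logprob_matrix
from .results import DegenerateClassError

ASSIGNMENT_RULES = ("modal", "proportional", "random")


@dataclass
class PosteriorMatrix:
    """P(X_ij = t | Y_ij), one row per unit."""

    post: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.post, dtype=float)
        if (p < -1e-12).any() or np.abs(p.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("posterior rows must be non-negative and sum to 1")
        self.post = p


@dataclass
class AssignmentWeights:
    """Assignment weights P(assigned = s | Y_ij) under a classification rule."""

    w: np.ndarray
    rule: str


@dataclass
class ClassificationErrorMatrix:
    """d[s, t] = P(assigned = s | true = t) plus the marginal P(X = t)."""

    d: np.ndarray
    marginal: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.marginal = np.asarray(self.marginal, dtype=float)
        if np.abs(self.d.sum(axis=0) - 1.0).max() > 1e-8:
            raise ValueError("columns of D must sum to 1")


def posterior_probs(params: SingleLevelParams, data: ItemResponseData) -> PosteriorMatrix:
    """Bayes-rule posteriors under the fitted simple LC model (log space)."""
    lp = np.log(params.class_props) + item_logprob_matrix(params.measurement, data.items)
    post = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
    return PosteriorMatrix(post)


def assign(post: PosteriorMatrix, rule: str = "modal", seed: int = 0) -> AssignmentWeights:
    """Convert posteriors to assignment weights.

    modal: one-hot at the argmax (ties to the lowest class index);
    proportional: the posterior itself; random: one-hot sampled per row.
    """
    if rule not in ASSIGNMENT_RULES:
        raise ValueError(f"unknown assignment rule {rule!r}; use one of {ASSIGNMENT_RULES}")
    P = post.post
    N, T = P.shape
    if rule == "proportional":
        return AssignmentWeights(P.copy(), rule)
    w = np.zeros_like(P)
    if rule == "modal":
        w[np.arange(N), P.argmax(axis=1)] = 1.0  # argmax takes the first maximum
    else:
        rng = np.random.default_rng(seed)
        u = rng.random(N)
        idx = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
        w[np.arange(N), np.minimum(idx, T - 1)] = 1.0
    return AssignmentWeights(w, rule)


def error_matrix(post: PosteriorMatrix, w: AssignmentWeights) -> ClassificationErrorMatrix:
    """Empirical classification-error matrix.

    d[s, t] = mean_i( post[i, t] * w[i, s] ) / mean_i( post[i, t] ).
    """
    P, W = post.post, w.w
    if P.shape != W.shape:
        raise ValueError("posterior and weights not conformable")
    N = P.shape[0]
    marginal = P.mean(axis=0)
    if (marginal < 1e-12).any():
        empty = np.where(marginal < 1e-12)[0] + 1
        raise DegenerateClassError(
            f"estimated class(es) {empty.tolist()} have (near-)zero marginal mass"
        )
    d = (W.T @ P) / N / marginal
    return ClassificationErrorMatrix(d, marginal)


def total_misclassification(cem: ClassificationErrorMatrix) -> float:
    """Prior-weighted probability of misassignment, sum_t P(X=t)(1 - d[t,t])."""
    return float(np.sum(cem.marginal * (1.0 - np.diag(cem.d))))


def clip_error_matrix(cem: ClassificationErrorMatrix, floor: float = 1e-6) -> ClassificationErrorMatrix:
    """Clip D entrywise away from zero and renormalize columns.

    Exact zeros arise under near-perfect separation and would contribute
    -inf log-likelihood terms in step 3.
    """
    d = np.clip(cem.d, floor, 1.0)
    d /= d.sum(axis=0, keepdims=True)
    return ClassificationErrorMatrix(d, cem.marginal)
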