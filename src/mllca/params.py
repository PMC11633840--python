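"""Parameter containers and multinomial-logit link functions.

Identification follows the usual reference-category convention: the first
higher-level class, the first lower-level class, and item response 0 are the
references, so alpha[0, :] = 0 and gamma[:, 0, :] = 0 are stored explicitly
and never counted as free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logit as _logit

EPS = 1e-10


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    logits = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=-1, keepdims=True)


@dataclass
class MeasurementParams:
    """Class-conditional item response probabilities phi[t, h] = P(Y_h=1 | X=t)."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim != 2:
            raise ValueError("phi must be T x H")
        self.phi = np.clip(phi, EPS, 1.0 - EPS)

    @property
    def n_classes(self) -> int:
        return self.phi.shape[0]

    @property
    def n_items(self) -> int:
        return self.phi.shape[1]

    @property
    def beta(self) -> np.ndarray:
        """Logit parametrization beta[t, h] = logit(phi[t, h])."""
        return _logit(self.phi)


@dataclass
class StructuralParams:
    """Logistic coefficients of the structural model.

    alpha : (M, 1 + p_H) — higher-level class model, row 0 is the zero
        reference slice; column 0 holds intercepts.
    gamma : (M, T, 1 + p_L + p_H) — lower-level class model given W=m;
        slice gamma[:, 0, :] is the zero reference; columns are
        (intercept, z_low coefficients, z_high coefficients).
    """

    alpha: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.array(self.alpha, dtype=float)
        self.gamma = np.array(self.gamma, dtype=float)
        if self.alpha.ndim != 2 or self.gamma.ndim != 3:
            raise ValueError("alpha must be M x (1+p_H); gamma M x T x (1+p_L+p_H)")
        if self.alpha.shape[0] != self.gamma.shape[0]:
            raise ValueError("alpha and gamma disagree on M")
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.gamma).all()):
            raise ValueError("structural coefficients must be finite")
        self.alpha[0, :] = 0.0
        self.gamma[:, 0, :] = 0.0

    @property
    def n_high(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_low(self) -> int:
        return self.gamma.shape[1]

    @property
    def p_high(self) -> int:
        return self.alpha.shape[1] - 1

    @property
    def p_low(self) -> int:
        return self.gamma.shape[2] - 1 - self.p_high


@dataclass
class ModelParams:
    """Bundle of measurement and structural parameters with matching T."""

    measurement: MeasurementParams
    structural: StructuralParams

    def __post_init__(self) -> None:
        if self.measurement.n_classes != self.structural.n_low:
            raise ValueError("measurement and structural parts disagree on T")


@dataclass
class SingleLevelParams:
    """Simple (single-level) latent class model: class proportions + phi."""

    class_props: np.ndarray
    measurement: MeasurementParams

    def __post_init__(self) -> None:
        p = np.asarray(self.class_props, dtype=float)
        if p.ndim != 1 or p.shape[0] != self.measurement.n_classes:
            raise ValueError("class_props must have length T")
        if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("class_props must be positive and sum to 1")
        self.class_props = p / p.sum()


# ----------------------------------------------------------------------
# Link functions
# ----------------------------------------------------------------------

def class_probs_high(structural: StructuralParams, z_high=()) -> np.ndarray:
    """P(W_j = m | Z^H_j) for one group: softmax of alpha @ (1, z_high).

    Class 1 (index 0) is the reference with zero logit.
    """
    zh = np.asarray(z_high, dtype=float).ravel()
    if not np.isfinite(zh).all():
        raise ValueError("z_high must be finite")
    if zh.shape[0] != structural.p_high:
        raise ValueError(f"expected {structural.p_high} higher-level covariates")
    x = np.concatenate(([1.0], zh))
    return _softmax_rows(structural.alpha @ x)


def class_probs_low(structural: StructuralParams, m: int, z_low=(), z_high=()) -> np.ndarray:
    """P(X_ij = t | W_j = m, Z_ij) for one unit; m is 0-based."""
    if not 0 <= m < structural.n_high:
        raise IndexError(f"higher-level class index {m} out of range")
    zl = np.asarray(z_low, dtype=float).ravel()
    zh = np.asarray(z_high, dtype=float).ravel()
    if zl.shape[0] != structural.p_low or zh.shape[0] != structural.p_high:
        raise ValueError("covariate dimensions disagree with structural params")
    x = np.concatenate(([1.0], zl, zh))
    return _softmax_rows(structural.gamma[m] @ x)


def class_probs_high_all(structural: StructuralParams, z_high: np.ndarray) -> np.ndarray:
    """Vectorized P(W=m | Z^H) for J groups -> (J, M)."""
    J = z_high.shape[0]
    X = np.column_stack([np.ones(J), z_high])
    return _softmax_rows(X @ structural.alpha.T)


def class_probs_low_all(
    structural: StructuralParams, z_low: np.ndarray, z_high_units: np.ndarray
) -> np.ndarray:
    """Vectorized P(X=t | W=m, Z) for N units -> (N, M, T)."""
    N = z_low.shape[0]
    X = np.column_stack([np.ones(N), z_low, z_high_units])
    logits = np.einsum("np,mtp->nmt", X, structural.gamma)
    return _softmax_rows(logits)


def item_logprob_matrix(measurement: MeasurementParams, items: np.ndarray) -> np.ndarray:
    """log P(Y_i | X=t) under local independence -> (N, T)."""
    lp = np.log(measurement.phi)
    lq = np.log1p(-measurement.phi)
    return items @ lp.T + (1 - items) @ lq.T


def item_prob(measurement: MeasurementParams, t: int, y) -> float:
    """log P(y | X=t) for a single binary response vector."""
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary")
    return float(item_logprob_matrix(measurement, y.reshape(1, -1))[0, t])


# ----------------------------------------------------------------------
# Free-parameter packing (identification slices excluded)
# ----------------------------------------------------------------------

def n_free_structural(structural: StructuralParams) -> int:
    M, T = structural.n_high, structural.n_low
    return (M - 1) * structural.alpha.shape[1] + M * (T - 1) * structural.gamma.shape[2]


def pack_structural(structural: StructuralParams) -> np.ndarray:
    return np.concatenate(
        [structural.alpha[1:].ravel(), structural.gamma[:, 1:, :].ravel()]
    )


def unpack_structural(theta: np.ndarray, template: StructuralParams) -> StructuralParams:
    M, T = template.n_high, template.n_low
    ca, cg = template.alpha.shape[1], template.gamma.shape[2]
    na = (M - 1) * ca
    alpha = np.zeros((M, ca))
    alpha[1:] = theta[:na].reshape(M - 1, ca)
    gamma = np.zeros((M, T, cg))
    gamma[:, 1:, :] = theta[na:].reshape(M, T - 1, cg)
    return StructuralParams(alpha=alpha, gamma=gamma)
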