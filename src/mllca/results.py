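"""Fit configuration, fit results, and error types shared by all estimators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class DegenerateClassError(RuntimeError):
    """An estimated class has (near-)zero probability mass."""


class SingularInformationError(RuntimeError):
    """The observed information matrix is not invertible."""

    def __init__(self, message: str, eigenvalues=None):
        super().__init__(message)
        self.eigenvalues = eigenvalues


@dataclass
class FitConfig:
    """EM settings.

    A short-run strategy keeps many random starts affordable: every start is
    run for `short_iters` iterations, then the `n_refine` best are iterated
    to convergence and the best final log-likelihood wins.
    """

    n_starts: int = 20
    max_iter: int = 1000
    tol: float = 1e-8
    seed: int = 0
    short_iters: int = 40
    n_refine: int = 3
    check_monotone: bool = False

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FitResult:
    """Estimates plus likelihood, SEs, and convergence metadata."""

    params: Any
    loglik: float
    converged: bool
    n_iter: int
    n_params: int
    se: np.ndarray | None = None
    vcov: np.ndarray | None = None
    bic: float | None = None
    free_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        out = {
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_params": int(self.n_params),
            "bic": None if self.bic is None else float(self.bic),
            "meta": {k: v for k, v in self.meta.items() if np.isscalar(v) or isinstance(v, (str, list, dict))},
        }
        if self.se is not None:
            out["se"] = dict(zip(self.free_names, np.asarray(self.se).round(6).tolist()))
        return out
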