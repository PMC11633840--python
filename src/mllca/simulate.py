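"""Synthetic-data generation and the Monte Carlo estimator comparison.

The generating design is a multilevel LC population with T=3 lower-level
classes, M=2 higher-level classes, H=10 binary items and one standard
normal lower-level covariate.  Item profiles are block-structured: class 1
answers 1 on all items with probability s, class 2 on the last five items
only, class 3 on none, with s in {0.7, 0.8, 0.9} (small / moderate / large
lower-level separation).  Higher-level separation is set through the
random intercepts so that at z = 0 the conditional class proportions are
(0.29, 0.33, 0.38) / (0.38, 0.33, 0.29) (moderate) or
(0.14, 0.32, 0.54) / (0.60, 0.25, 0.15) (large), with omega = (0.6, 0.4).
Covariate slopes are (-0.25, -0.25) in W=1 and (+0.25, +0.25) in W=2, or
all zero in the null arm used for size/power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ItemResponseData
from .engine import ItemKernel, FixedDKernel, permute_params
from .estimators import one_step, three_step, two_step, slope_indices, standard_errors
from .params import (
    MeasurementParams,
    ModelParams,
    StructuralParams,
    class_probs_low_all,
    pack_structural,
)
from .results import FitConfig
from .selection import r2_from_params

LL_SEPARATION = {"small": 0.7, "moderate": 0.8, "large": 0.9}
HL_PROPORTIONS = {
    "moderate": np.array([[0.29, 0.33, 0.38], [0.38, 0.33, 0.29]]),
    "large": np.array([[0.14, 0.32, 0.54], [0.60, 0.25, 0.15]]),
}
OMEGA = np.array([0.6, 0.4])
SLOPES = np.array([[0.0, -0.25, -0.25], [0.0, 0.25, 0.25]])
N_ITEMS = 10


@dataclass
class SimulationCondition:
    """One cell of the simulation grid."""

    n_j: int
    J: int
    ll_sep: str
    hl_sep: str
    slopes: str = "nonzero"  # or "zero"

    def __post_init__(self):
        import warnings

        if self.n_j not in (100, 500) or self.J not in (30, 50, 100):
            warnings.warn("sample sizes outside the standard design grid")
        if self.ll_sep not in LL_SEPARATION or self.hl_sep not in HL_PROPORTIONS:
            raise ValueError("unknown separation level")

    @property
    def label(self) -> str:
        return f"n_j={self.n_j},J={self.J},LL={self.ll_sep},HL={self.hl_sep},slopes={self.slopes}"


def build_population(ll_sep: str, hl_sep: str, slopes: str = "nonzero") -> ModelParams:
    """Fully instantiated generating parameters for one design cell."""
    s = LL_SEPARATION[ll_sep]
    phi = np.vstack(
        [
            np.full(N_ITEMS, s),
            np.concatenate([np.full(5, 1 - s), np.full(5, s)]),
            np.full(N_ITEMS, 1 - s),
        ]
    )
    pi = HL_PROPORTIONS[hl_sep]
    gamma = np.zeros((2, 3, 2))
    gamma[:, :, 0] = np.log(pi / pi[:, [0]])
    if slopes == "nonzero":
        gamma[:, :, 1] = SLOPES
    elif slopes != "zero":
        raise ValueError("slopes must be 'nonzero' or 'zero'")
    alpha = np.array([[0.0], [np.log(OMEGA[1] / OMEGA[0])]])
    return ModelParams(
        measurement=MeasurementParams(phi),
        structural=StructuralParams(alpha=alpha, gamma=gamma),
    )


def simulate_dataset(pop: ModelParams, n_j: int, J: int, seed):
    """Draw one dataset; returns (data, true_w (J,), true_x (N,))."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M, T = pop.structural.n_high, pop.structural.n_low
    omega = np.exp(pop.structural.alpha[:, 0])
    omega /= omega.sum()
    N = n_j * J
    w = rng.choice(M, size=J, p=omega)
    z = rng.standard_normal(N)
    group = np.repeat(np.arange(J), n_j)
    px = class_probs_low_all(
        pop.structural, z[:, None], np.empty((N, 0))
    )  # (N, M, T)
    pxw = px[np.arange(N), w[group], :]
    u = rng.random(N)
    x = (pxw.cumsum(axis=1) < u[:, None]).sum(axis=1)
    items = (rng.random((N, N_ITEMS)) < pop.measurement.phi[x]).astype(np.int8)
    data = ItemResponseData(items=items, group_id=group, z_low=z[:, None])
    return data, w, x


# ----------------------------------------------------------------------
# Label alignment against the generating population
# ----------------------------------------------------------------------

def _greedy_match(cost: np.ndarray) -> np.ndarray:
    """perm[new] = old minimizing cost[old, new] greedily."""
    K = cost.shape[0]
    perm = -np.ones(K, dtype=int)
    rows, cols = set(range(K)), set(range(K))
    for _ in range(K):
        _, r, c = min((cost[r, c], r, c) for r in rows for c in cols)
        perm[c] = r
        rows.discard(r)
        cols.discard(c)
    return perm


def align_to_population(fit_params: ModelParams, pop: ModelParams, align_lower=True) -> ModelParams:
    """Permute class labels to the population layout.

    Lower-level classes are matched on mean absolute difference in phi;
    higher-level classes on L1 distance between the conditional class
    proportions at z = 0.
    """
    if align_lower:
        cost_t = np.abs(
            fit_params.measurement.phi[:, None, :] - pop.measurement.phi[None, :, :]
        ).mean(axis=2)
        perm_t = _greedy_match(cost_t)
        fit_params = permute_params(fit_params, perm_t=perm_t)

    def pi0(params):
        g = params.structural.gamma[:, :, 0]
        p = np.exp(g - g.max(axis=1, keepdims=True))
        return p / p.sum(axis=1, keepdims=True)

    cost_m = np.abs(pi0(fit_params)[:, None, :] - pi0(pop)[None, :, :]).sum(axis=2)
    perm_m = _greedy_match(cost_m)
    return permute_params(fit_params, perm_m=perm_m)


def extract_slopes(params: ModelParams) -> np.ndarray:
    """The four lower-level covariate slopes, ordered (m=1: t=2, t=3; m=2: ...)."""
    theta = pack_structural(params.structural)
    return theta[slope_indices(params.structural)]


# ----------------------------------------------------------------------
# Monte Carlo study
# ----------------------------------------------------------------------

ESTIMATORS = ("one_step", "two_step", "three_step", "three_step_naive")


@dataclass
class StudySummary:
    """Per condition x estimator bias / SD / SE quality / coverage table."""

    table: pd.DataFrame
    estimates: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _fit_estimator(name, data, config, pop):
    T, M = pop.structural.n_low, pop.structural.n_high
    if name == "one_step":
        fit = one_step(data, T, M, config=config)
        kernel = ItemKernel()
    elif name == "two_step":
        fit = two_step(data, T, M, config=config)
        kernel = ItemKernel(fixed_phi=None)  # replaced after alignment
    elif name in ("three_step", "three_step_naive"):
        fit = three_step(
            data, T, M, rule="modal", config=config,
            correction=(name == "three_step"),
            phi_ref=pop.measurement.phi,
        )
        kernel = None
    else:
        raise ValueError(f"unknown estimator {name!r}")
    return fit, kernel


def run_study(
    conditions,
    estimators=("one_step", "two_step", "three_step"),
    reps: int = 100,
    seed: int = 0,
    config: FitConfig | None = None,
    compute_se=("three_step",),
    r2: bool = True,
) -> StudySummary:
    """Simulate, fit, align, and aggregate over replications.

    `compute_se` lists the estimators for which observed-information SEs
    (and hence coverage / rejection rates) are computed; SEs are the main
    runtime cost for the one-step estimator.
    """
    base = config or FitConfig()
    rows = []
    estimates: dict = {}
    compute_se = set(estimators if compute_se == "all" else compute_se)

    for cond in conditions:
        pop = build_population(cond.ll_sep, cond.hl_sep, cond.slopes)
        truth = extract_slopes(pop)
        ss = np.random.SeedSequence([seed, cond.n_j, cond.J,
                                     list(LL_SEPARATION).index(cond.ll_sep),
                                     list(HL_PROPORTIONS).index(cond.hl_sep)])
        child_seeds = ss.generate_state(reps) % (2**31 - 1)
        per_est = {e: {"est": [], "se": []} for e in estimators}
        r2_low_vals, r2_high_vals = [], []
        n_fail = {e: 0 for e in estimators}

        for r in range(reps):
            rng = np.random.default_rng(child_seeds[r])
            data, w_true, x_true = simulate_dataset(pop, cond.n_j, cond.J, rng)
            if r2:
                rl, rh = r2_from_params(pop, data)
                r2_low_vals.append(rl)
                r2_high_vals.append(rh)
            for est in estimators:
                cfg = FitConfig(
                    n_starts=base.n_starts, max_iter=base.max_iter, tol=base.tol,
                    short_iters=base.short_iters, n_refine=base.n_refine,
                    seed=int(rng.integers(2**31 - 1)),
                )
                try:
                    fit, kernel = _fit_estimator(est, data, cfg, pop)
                    aligned = align_to_population(
                        fit.params, pop,
                        align_lower=not est.startswith("three_step"),
                    )
                    fit.params = aligned
                    slopes = extract_slopes(aligned)
                    ses = np.full(4, np.nan)
                    if est in compute_se:
                        if est == "one_step":
                            standard_errors(fit, data, ItemKernel(), which="all")
                        elif est == "two_step":
                            standard_errors(
                                fit, data, ItemKernel(fixed_phi=aligned.measurement.phi)
                            )
                        else:
                            standard_errors(fit, data, fit.meta["_kernel"])
                        ses = np.asarray(fit.se)[slope_indices(aligned.structural)]
                    per_est[est]["est"].append(slopes)
                    per_est[est]["se"].append(ses)
                except Exception:
                    n_fail[est] += 1

        for est in estimators:
            E = np.array(per_est[est]["est"])
            S = np.array(per_est[est]["se"])
            estimates[(cond.label, est)] = {"est": E, "se": S, "truth": truth}
            if E.size == 0:
                continue
            mean_est = E.mean(axis=0)
            sd = E.std(axis=0, ddof=1)
            if np.all(truth != 0):
                rel_bias = float(np.mean(np.abs(mean_est - truth) / np.abs(truth)))
            else:
                rel_bias = np.nan
            abs_bias = float(np.mean(np.abs(mean_est - truth)))
            row = {
                "condition": cond.label, "n_j": cond.n_j, "J": cond.J,
                "ll_sep": cond.ll_sep, "hl_sep": cond.hl_sep,
                "slopes": cond.slopes, "estimator": est,
                "reps_used": E.shape[0], "n_fail": n_fail[est],
                "mean_rel_abs_bias": rel_bias, "mean_abs_bias": abs_bias,
                "mc_sd": float(sd.mean()),
            }
            if np.isfinite(S).all() and S.size:
                mean_se = S.mean(axis=0)
                row["mean_se"] = float(mean_se.mean())
                row["se_sd_ratio"] = float((mean_se / sd).mean())
                cover = np.abs(E - truth) <= 1.959963984540054 * S
                row["coverage_95"] = float(cover.mean())
                reject = np.abs(E / S) > 1.959963984540054
                row["rejection_rate"] = float(reject.mean())
            if r2 and r2_low_vals:
                row["r2_entropy_low"] = float(np.mean(r2_low_vals))
                row["r2_entropy_high"] = float(np.mean(r2_high_vals))
            rows.append(row)

    return StudySummary(table=pd.DataFrame(rows), estimates=estimates)
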