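"""Class enumeration: BIC, entropy-based R-squared, sequential and
simultaneous selection of (T, M).

The entropy R-squared measures class separation at either level:

    R2 = 1 - mean posterior entropy / entropy of the marginal class
         distribution

(natural logs), so 0 means the responses carry no information about class
membership and 1 means classification is certain.  The default in this
package computes it from a fitted multilevel measurement model (no
covariates), the quantity latent-class software reports alongside a fit;
posteriors under externally supplied (e.g. generating) parameters are
available through the lower-level functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ItemResponseData
from .engine import ItemKernel, e_step, ml_em_fit
from .params import ModelParams
from .results import FitConfig, FitResult
from .single_level import sl_em_fit


def bic(fit: FitResult, n_effective: int) -> float:
    """Bayesian information criterion -2*loglik + k*log(n_effective)."""
    return -2.0 * fit.loglik + fit.n_params * np.log(n_effective)


def _entropy_rows(p: np.ndarray) -> np.ndarray:
    q = np.clip(p, 1e-300, None)
    return -(p * np.log(q)).sum(axis=-1)


def entropy_r2(post: np.ndarray, marginal: np.ndarray) -> float:
    """Entropy R-squared of a posterior matrix against a marginal."""
    marginal = np.asarray(marginal, dtype=float)
    if (marginal >= 1.0 - 1e-12).any():
        raise ValueError("degenerate marginal: a class has probability one")
    denom = _entropy_rows(marginal)
    r2 = 1.0 - _entropy_rows(np.asarray(post)).mean() / denom
    return float(np.clip(r2, 0.0, 1.0))


def entropy_r2_lower(post, marginal) -> float:
    """Lower-level R2 from unit posteriors P(X_ij=t | data)."""
    post = getattr(post, "post", post)
    return entropy_r2(post, marginal)


def entropy_r2_higher(pw: np.ndarray, omega: np.ndarray) -> float:
    """Higher-level R2 from group posteriors P(W_j=m | group data)."""
    return entropy_r2(pw, omega)


def r2_from_params(params: ModelParams, data: ItemResponseData, kernel=None):
    """(lower R2, higher R2) from posteriors under the given parameters.

    Lower-level posteriors are the marginal P(X_ij=t | Y_j, Z), i.e. they
    use the group and covariate information; the lower-level marginal
    averages P(X|W,Z) over classes and the observed covariates.
    """
    from .engine import FixedDKernel  # noqa: F401  (documented alternative)
    from .params import class_probs_high_all, class_probs_low_all

    kernel = kernel or ItemKernel(fixed_phi=params.measurement.phi)
    post = e_step(params, data, kernel)
    pw_units = np.repeat(post.pw, data.group_sizes, axis=0)
    q = np.einsum("nm,nmt->nt", pw_units, post.pxw)

    zh = data.z_high if data.z_high is not None else np.empty((data.n_groups, 0))
    om = class_probs_high_all(params.structural, zh)  # (J, M)
    px = class_probs_low_all(
        params.structural, data.z_low_matrix(), data.z_high_per_unit()
    )  # (N, M, T)
    om_units = np.repeat(om, data.group_sizes, axis=0)
    p_marg = (om_units[:, :, None] * px).sum(axis=1).mean(axis=0)
    omega = om.mean(axis=0)
    return entropy_r2(q, p_marg), entropy_r2(post.pw, omega)


def r2_from_measurement_fit(fit: FitResult, data: ItemResponseData):
    """(lower R2, higher R2) from a fitted covariate-free multilevel model."""
    meas_data = ItemResponseData(items=data.items, group_id=data.group_index)
    return r2_from_params(fit.params, meas_data)


@dataclass
class SelectionTrace:
    """Grid of candidate fits with their BICs, for audit."""

    records: list = field(default_factory=list)

    def add(self, stage, T, M, fit, n_eff):
        self.records.append(
            {"stage": stage, "T": T, "M": M, "loglik": fit.loglik,
             "n_params": fit.n_params, "n_effective": n_eff,
             "bic": bic(fit, n_eff)}
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def sequential_select(
    data: ItemResponseData, T_range, M_range, config: FitConfig | None = None
):
    """Hierarchical selection: pick T with M=1, then M at that T, then
    re-pick T at the selected M.  Returns ((T, M), trace)."""
    config = config or FitConfig()
    T_range, M_range = list(T_range), list(M_range)
    if not T_range or not M_range:
        raise ValueError("empty selection range")
    trace = SelectionTrace()
    meas = ItemResponseData(items=data.items, group_id=data.group_index)

    def fit_tm(T, M, stage, n_eff):
        if M == 1:
            f = sl_em_fit(meas, T, config=config)
        else:
            f = ml_em_fit(meas, T, M, ItemKernel(), config=config)
        trace.add(stage, T, M, f, n_eff)
        return bic(f, n_eff)

    # stage 1: T with M=1, n_effective = N
    bics = {T: fit_tm(T, 1, "T|M=1", data.n_units) for T in T_range}
    T_sel = min(bics, key=bics.get)
    # stage 2: M at fixed T, n_effective = J
    bics = {M: fit_tm(T_sel, M, "M|T", data.n_groups) for M in M_range}
    M_sel = min(bics, key=bics.get)
    # stage 3: re-pick T at fixed M, n_effective = N
    bics = {T: fit_tm(T, M_sel, "T|M", data.n_units) for T in T_range}
    T_sel = min(bics, key=bics.get)
    return (T_sel, M_sel), trace


def simultaneous_select(
    data: ItemResponseData, T_range, M_range, config: FitConfig | None = None
):
    """Full-grid selection by BIC (n_effective = N). Returns ((T, M), trace)."""
    config = config or FitConfig()
    T_range, M_range = list(T_range), list(M_range)
    if not T_range or not M_range:
        raise ValueError("empty selection range")
    trace = SelectionTrace()
    meas = ItemResponseData(items=data.items, group_id=data.group_index)
    best = None
    for T in T_range:
        for M in M_range:
            if M == 1:
                f = sl_em_fit(meas, T, config=config)
            else:
                f = ml_em_fit(meas, T, M, ItemKernel(), config=config)
            b = bic(f, data.n_units)
            trace.add("grid", T, M, f, data.n_units)
            if best is None or b < best[0]:
                best = (b, T, M)
    return (best[1], best[2]), trace
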