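import itertools

import numpy as np
import pytest

from mllca import (
    ItemResponseData,
    MeasurementParams,
    ModelParams,
    SingleLevelParams,
    StructuralParams,
    build_population,
    simulate_dataset,
)
from mllca.params import class_probs_high, class_probs_low, item_logprob_matrix


@pytest.fixture(scope="session")
def tiny_instance():
    """J=2 groups of 2 units, H=2 items, T=M=2, both covariate levels.

    Small enough for exhaustive enumeration over all latent configurations.
    """
    rng = np.random.default_rng(5)
    J, nj, H, T, M = 2, 2, 2, 2, 2
    items = rng.integers(0, 2, size=(J * nj, H))
    z = rng.standard_normal(J * nj)
    zh = rng.standard_normal(J)
    data = ItemResponseData(
        items=items, group_id=np.repeat([0, 1], nj), z_low=z[:, None], z_high=zh[:, None]
    )
    phi = np.array([[0.8, 0.3], [0.2, 0.6]])
    alpha = np.array([[0.0, 0.0], [0.4, -0.3]])
    gamma = np.zeros((M, T, 3))
    gamma[:, 1, :] = rng.normal(0, 0.5, (M, 3))
    params = ModelParams(MeasurementParams(phi), StructuralParams(alpha, gamma))
    return data, params


def brute_force_loglik(params: ModelParams, data: ItemResponseData) -> float:
    """Likelihood by explicit summation over all (W_j, X_1j, ..., X_njj)."""
    M = params.structural.n_high
    T = params.structural.n_low
    ll = 0.0
    for j in range(data.n_groups):
        lo = data.group_starts[j]
        hi = lo + data.group_sizes[j]
        ys, zs = data.items[lo:hi], data.z_low[lo:hi]
        zh = data.z_high[j] if data.z_high is not None else ()
        nj = hi - lo
        pj = 0.0
        for m in range(M):
            pw = class_probs_high(params.structural, zh)[m]
            for xs in itertools.product(range(T), repeat=nj):
                term = pw
                for i, xi in enumerate(xs):
                    zl = zs[i] if zs is not None else ()
                    px = class_probs_low(params.structural, m, zl, zh)[xi]
                    py = np.exp(item_logprob_matrix(params.measurement, ys[i : i + 1]))[0, xi]
                    term *= px * py
                pj += term
        ll += np.log(pj)
    return ll


@pytest.fixture(scope="session")
def pattern_world():
    """All 2^3 response patterns for a well-separated 3-item, 3-class model.

    Provides exact P(Y|X), step-1 posteriors, modal assignments, and the
    pattern-enumeration classification-error matrix.
    """
    pop = build_population("large", "large")
    phi3 = pop.measurement.phi[:, [0, 4, 9]]
    slp = SingleLevelParams(np.array([0.3, 0.35, 0.35]), MeasurementParams(phi3))
    pats = np.array(list(itertools.product([0, 1], repeat=3)))
    py_t = np.exp(item_logprob_matrix(slp.measurement, pats))  # (8, T)
    post = slp.class_props * py_t
    post /= post.sum(axis=1, keepdims=True)
    assign_pat = post.argmax(axis=1)
    D = np.zeros((3, 3))
    for s in range(3):
        D[s] = py_t[assign_pat == s].sum(axis=0)
    return {
        "pop": pop, "slp": slp, "patterns": pats, "py_t": py_t,
        "post": post, "assign": assign_pat, "D": D,
    }


@pytest.fixture(scope="session")
def large_sep_dataset():
    """One condition-31 style dataset (n_j=100, J=30, large/large)."""
    pop = build_population("large", "large")
    data, w, x = simulate_dataset(pop, 100, 30, 42)
    return pop, data, w, x
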