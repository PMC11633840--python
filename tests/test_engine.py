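import itertools

import numpy as np
import pytest

from mllca import (
    FitConfig,
    FixedDKernel,
    ItemKernel,
    ItemResponseData,
    MeasurementParams,
    ModelParams,
    SingleLevelParams,
    StructuralParams,
    build_population,
    e_step,
    ml_em_fit,
    ml_loglik,
    permute_params,
    simulate_dataset,
    sl_loglik,
)
from mllca.params import class_probs_low, n_free_structural

from conftest import brute_force_loglik


def test_loglik_matches_exhaustive_enumeration(tiny_instance):
    data, params = tiny_instance
    ll = ml_loglik(params, data, ItemKernel())
    assert ll == pytest.approx(brute_force_loglik(params, data), abs=1e-10)


def test_single_higher_class_collapses_to_simple_model():
    pop = build_population("moderate", "moderate")
    data, _, _ = simulate_dataset(pop, 30, 5, 0)
    data = ItemResponseData(items=data.items, group_id=data.group_index)  # drop z
    phi = pop.measurement.phi
    props = np.array([0.3, 0.3, 0.4])
    gamma = np.zeros((1, 3, 1))
    gamma[0, :, 0] = np.log(props / props[0])
    params = ModelParams(
        MeasurementParams(phi), StructuralParams(np.zeros((1, 1)), gamma)
    )
    slp = SingleLevelParams(props, MeasurementParams(phi))
    assert ml_loglik(params, data, ItemKernel()) == pytest.approx(
        sl_loglik(slp, data), abs=1e-8
    )


def test_e_step_matches_enumeration(tiny_instance):
    data, params = tiny_instance
    post = e_step(params, data, ItemKernel())
    M, T, nj = 2, 2, 2
    from mllca.params import class_probs_high, item_logprob_matrix

    pw = np.zeros((2, M))
    for j in range(2):
        ys = data.items[j * nj : (j + 1) * nj]
        zs = data.z_low[j * nj : (j + 1) * nj]
        for m in range(M):
            p = class_probs_high(params.structural, data.z_high[j])[m]
            for xs in itertools.product(range(T), repeat=nj):
                term = p
                for i, xi in enumerate(xs):
                    term *= (
                        class_probs_low(params.structural, m, zs[i], data.z_high[j])[xi]
                        * np.exp(item_logprob_matrix(params.measurement, ys[i : i + 1]))[0, xi]
                    )
                pw[j, m] += term
    pw /= pw.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(post.pw, pw, atol=1e-10)
    assert np.abs(post.pw.sum(axis=1) - 1).max() < 1e-12
    assert np.abs(post.pxw.sum(axis=2) - 1).max() < 1e-12


def test_identical_structural_rows_give_uniform_group_posterior():
    pop = build_population("moderate", "moderate")
    data, _, _ = simulate_dataset(pop, 20, 4, 1)
    gamma = pop.structural.gamma.copy()
    gamma[1] = gamma[0]
    params = ModelParams(
        pop.measurement,
        StructuralParams(np.zeros((2, 1)), gamma),
    )
    post = e_step(params, data, ItemKernel())
    np.testing.assert_allclose(post.pw, 0.5, atol=1e-12)


def test_group_posteriors_approach_certainty_with_group_size():
    pop = build_population("large", "large")
    data, w, _ = simulate_dataset(pop, 500, 10, 3)
    post = e_step(pop, data, ItemKernel())
    assert post.pw.max(axis=1).min() > 0.999


def test_fixed_d_identity_kernel_equals_true_label_likelihood(pattern_world):
    """With D = I the assignment is treated as a perfectly measured
    indicator: the likelihood equals the multilevel model of the labels."""
    pop = pattern_world["pop"]
    rng = np.random.default_rng(8)
    n = 40
    x = rng.integers(0, 3, n)
    z = rng.standard_normal(n)
    w = np.zeros((n, 3))
    w[np.arange(n), x] = 1.0
    data = ItemResponseData(
        items=np.zeros((n, 1), int), group_id=np.repeat(np.arange(4), 10), z_low=z[:, None]
    )
    kernel = FixedDKernel(np.eye(3) * (1 - 3e-6) + 1e-6, w)
    ll = ml_loglik(pop, data, kernel)
    # direct: sum_j log sum_m om_m prod_i P(X=x_i | m, z_i)
    from mllca.params import class_probs_high

    om = class_probs_high(pop.structural, [])
    direct = 0.0
    for j in range(4):
        pj = 0.0
        for m in range(2):
            term = om[m]
            for i in range(j * 10, (j + 1) * 10):
                term *= class_probs_low(pop.structural, m, [z[i]])[x[i]]
            pj += term
        direct += np.log(pj)
    assert ll == pytest.approx(direct, rel=1e-5)


def test_step3_correction_identity_on_pattern_world(pattern_world):
    """P(assigned class | Z) from the fixed-D kernel equals brute-force
    marginalization over W, X, and all 2^H response patterns."""
    pw = pattern_world
    pop, py_t, assign_pat = pw["pop"], pw["py_t"], pw["assign"]
    phi3 = pw["slp"].measurement.phi
    struct = pop.structural
    rng = np.random.default_rng(5)
    nj, J = 3, 2
    pat_idx = rng.integers(0, 8, nj * J)
    z = rng.standard_normal(nj * J)
    labels = assign_pat[pat_idx]
    w = np.zeros((nj * J, 3))
    w[np.arange(nj * J), labels] = 1.0
    data = ItemResponseData(
        items=pw["patterns"][pat_idx], group_id=np.repeat([0, 1], nj), z_low=z[:, None]
    )
    ll_fd = ml_loglik(
        ModelParams(MeasurementParams(phi3), struct), data, FixedDKernel(pw["D"], w)
    )
    om = np.exp(struct.alpha[:, 0])
    om /= om.sum()
    ll_bf = 0.0
    for j in range(J):
        pj = 0.0
        for m in range(2):
            term = om[m]
            for i in range(j * nj, (j + 1) * nj):
                px = class_probs_low(struct, m, [z[i]])
                term *= sum(
                    px[t] * py_t[y, t] * (assign_pat[y] == labels[i])
                    for t in range(3)
                    for y in range(8)
                )
            pj += term
        ll_bf += np.log(pj)
    assert ll_fd == pytest.approx(ll_bf, abs=1e-10)


def test_em_monotone_for_both_kernels():
    pop = build_population("moderate", "large")
    data, _, x = simulate_dataset(pop, 50, 10, 6)
    cfg = FitConfig(seed=1, n_starts=4, check_monotone=True)
    fit = ml_em_fit(data, 3, 2, ItemKernel(), config=cfg)
    path = np.array(fit.meta["loglik_path"])
    assert (np.diff(path) >= -1e-8 * (1 + np.abs(path[:-1]))).all()

    w = np.zeros((data.n_units, 3))
    w[np.arange(data.n_units), x] = 1.0
    d = np.full((3, 3), 0.05) + np.eye(3) * 0.85
    fit2 = ml_em_fit(data, 3, 2, FixedDKernel(d, w), config=cfg)
    path2 = np.array(fit2.meta["loglik_path"])
    assert (np.diff(path2) >= -1e-8 * (1 + np.abs(path2[:-1]))).all()


def test_oracle_indicator_recovers_structural_parameters():
    """True labels as a perfect indicator: structural estimates close to truth."""
    pop = build_population("large", "large")
    data, w_true, x = simulate_dataset(pop, 200, 50, 12)
    wmat = np.zeros((data.n_units, 3))
    wmat[np.arange(data.n_units), x] = 1.0
    d = np.eye(3) * (1 - 3e-6) + 1e-6
    fit = ml_em_fit(data, 3, 2, FixedDKernel(d, wmat), config=FitConfig(seed=2, n_starts=5))
    from mllca import align_to_population, extract_slopes

    aligned = align_to_population(fit.params, pop, align_lower=False)
    slopes = extract_slopes(aligned)
    assert np.abs(slopes - [-0.25, -0.25, 0.25, 0.25]).max() < 0.12


def test_parameter_count_rule(tiny_instance):
    data, params = tiny_instance
    cfg = FitConfig(seed=0, n_starts=2, max_iter=50)
    fit_items = ml_em_fit(data, 2, 2, ItemKernel(), config=cfg)
    # (M-1)(1+pH) + M(T-1)(1+pL+pH) + T*H
    assert fit_items.n_params == 1 * 2 + 2 * 1 * 3 + 2 * 2
    w = np.tile([1.0, 0.0], (data.n_units, 1))
    fit_d = ml_em_fit(data, 2, 2, FixedDKernel(np.array([[0.9, 0.2], [0.1, 0.8]]), w), config=cfg)
    assert fit_d.n_params == 1 * 2 + 2 * 1 * 3


def test_relabeling_preserves_likelihood(tiny_instance):
    data, params = tiny_instance
    ll = ml_loglik(params, data, ItemKernel())
    for perm_t, perm_m in (([1, 0], None), (None, [1, 0]), ([1, 0], [1, 0])):
        permuted = permute_params(params, perm_t=perm_t, perm_m=perm_m)
        assert ml_loglik(permuted, data, ItemKernel()) == pytest.approx(ll, abs=1e-9)
    assert n_free_structural(params.structural) == n_free_structural(
        permute_params(params, perm_t=[1, 0]).structural
    )
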