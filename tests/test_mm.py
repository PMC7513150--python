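import math

import numpy as np
import pytest
from scipy import optimize

import relgamma as rg
from relgamma import (GammaObjective, RegressionData, compute_weights,
                      fit_gre_mle, fit_hybrid, fit_mm, gre_loss_value,
                      inner_minimize, majorizer1, majorizer2)
from relgamma.mm import _xtbx


# ----------------------------------------------------------------- weights
def test_weights_uniform_for_identical_observations(lpre_model):
    data = RegressionData(np.ones((6, 1)), np.full(6, 2.0))
    obj = GammaObjective(lpre_model, data, 0.5)
    w = compute_weights(obj, np.zeros(1))
    np.testing.assert_allclose(w, np.full(6, 1 / 6), rtol=1e-14)


def test_gross_outlier_gets_negligible_weight(lpre_model):
    y = np.array([1.0, 1.2, 0.8, 1e6])       # last point is y = 1e6 * t
    data = RegressionData(np.ones((4, 1)), y)
    obj = GammaObjective(lpre_model, data, 0.5)
    w = compute_weights(obj, np.zeros(1))
    assert w[-1] < 1e-10


def test_weights_sum_to_one(lpre_model, contaminated_data, rng):
    obj = GammaObjective(lpre_model, contaminated_data, 0.5)
    for _ in range(5):
        w = compute_weights(obj, rng.normal(size=3))
        assert abs(w.sum() - 1.0) < 1e-14
        assert np.all(w >= 0)


# -------------------------------------------------------------- majorizers
def test_majorizer1_tangency_and_dominance(lpre_model, clean_data, rng):
    obj = GammaObjective(lpre_model, clean_data, 0.5)
    bt = rng.normal(size=3)
    assert majorizer1(obj, bt, bt) == pytest.approx(obj.ell1(bt),
                                                    abs=1e-10)
    for _ in range(100):
        b = rng.normal(scale=2.0, size=3)
        assert majorizer1(obj, b, bt) >= obj.ell1(b) - 1e-10


def test_majorizer2_tangency_and_dominance(lpre_model, clean_data, rng):
    obj = GammaObjective(lpre_model, clean_data, 0.5)
    bt = rng.normal(size=3)
    assert majorizer2(obj, bt, bt) == pytest.approx(obj.ell2(bt),
                                                    abs=1e-10)
    for _ in range(100):
        b = rng.normal(scale=2.0, size=3)
        assert majorizer2(obj, b, bt) >= obj.ell2(b) - 1e-10


def test_majorizer2_hessian_psd(clean_data):
    g = 0.5
    H = g * g / (1 + g) * _xtbx(clean_data.X)
    eigs = np.linalg.eigvalsh(H)
    assert eigs.min() >= -1e-10


def test_xtbx_equals_half_centered_gram(rng):
    X = rng.normal(size=(50, 4))
    n = X.shape[0]
    B = 0.5 * (np.eye(n) - np.ones((n, n)) / n)
    np.testing.assert_allclose(_xtbx(X), X.T @ B @ X, atol=1e-10)


def test_majorizer1_single_observation_is_neg_log_density(lpre_model):
    data = RegressionData(np.array([[0.8]]), np.array([1.7]))
    obj = GammaObjective(lpre_model, data, 0.5)
    bt = np.array([0.3])
    for b in (np.array([0.0]), np.array([1.0]), np.array([-0.7])):
        expected = -float(obj.log_f(b)[0])  # w1 = 1, C = 0
        assert majorizer1(obj, b, bt) == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------- inner minimizer
def test_inner_minimizer_decreases_surrogate(lpre_model, contaminated_data,
                                             rng):
    obj = GammaObjective(lpre_model, contaminated_data, 0.5)
    bt = rng.normal(size=3)
    b_new = inner_minimize(obj, bt)
    before = majorizer1(obj, bt, bt) + majorizer2(obj, bt, bt)
    after = majorizer1(obj, b_new, bt) + majorizer2(obj, b_new, bt)
    assert after <= before + 1e-12


def test_inner_minimizer_matches_simplex_oracle(lpre_model, rng):
    """Derivative-free Nelder-Mead on the same surrogate must land on the
    same point (2-parameter toy)."""
    X = rng.normal(size=(25, 2))
    y = np.exp(X @ np.array([0.8, -0.3])) * rng.uniform(0.5, 2, 25)
    obj = GammaObjective(lpre_model, RegressionData(X, y), 0.5)
    bt = np.array([0.2, 0.1])
    b_newton = inner_minimize(obj, bt)

    def surrogate(b):
        return majorizer1(obj, b, bt) + majorizer2(obj, b, bt)

    res = optimize.minimize(surrogate, bt, method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": 1e-12,
                                     "maxiter": 2000})
    np.testing.assert_allclose(b_newton, res.x, atol=1e-5)


def test_inner_minimizer_small_gamma_is_weighted_mle_step(lpre_model, rng):
    """As gamma -> 0 the quadratic ell2-surrogate flattens, so the inner
    problem tends to the w-weighted GRE fit."""
    X = rng.normal(size=(30, 2))
    y = np.exp(X @ np.array([0.5, 0.5])) * rng.uniform(0.5, 2, 30)
    data = RegressionData(X, y)
    obj = GammaObjective(lpre_model, data, 1e-6)
    bt = np.array([0.3, 0.6])
    b_inner = inner_minimize(obj, bt)
    w = compute_weights(obj, bt)

    def weighted_gre(b):
        eps = y * np.exp(-X @ b)
        return float(np.sum(w * (eps + 1 / eps - 2)))

    res = optimize.minimize(weighted_gre, bt, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-14})
    np.testing.assert_allclose(b_inner, res.x, atol=1e-4)


# ------------------------------------------------------------------ fit_mm
def test_mm_trace_monotone_on_contaminated_instances(lpre_model):
    for seed in range(10):
        cfg = rg.model1_config(n=100, delta=0.15, seed=seed)
        data, _ = rg.simulate_dataset(cfg, model=lpre_model)
        obj = GammaObjective(lpre_model, data, 0.5)
        res = fit_mm(obj)
        assert res.converged
        assert np.all(np.diff(res.objective_trace) <= 1e-12)


def test_mm_small_gamma_matches_gre_minimizer(lpre_model, clean_data):
    obj = GammaObjective(lpre_model, clean_data, 1e-4)
    res = fit_mm(obj)
    b_gre = fit_gre_mle("lpre", clean_data)
    np.testing.assert_allclose(res.beta, b_gre, atol=1e-4)


def test_mm_matches_dense_grid_search_2d(lpre_model, rng):
    """p=2 oracle: the MM minimizer agrees with a dense 2-D grid search of
    the objective to grid resolution."""
    X = rng.normal(size=(60, 2))
    y = np.exp(X @ np.array([0.7, -0.4])) * rng.uniform(0.5, 2, 60)
    y[:6] = rng.lognormal(5.0, 1.0, 6)          # some gross outliers
    data = RegressionData(X, y)
    obj = GammaObjective(lpre_model, data, 0.5)
    res = fit_mm(obj, tol=1e-12)
    step = 1e-3
    b1 = np.arange(res.beta[0] - 0.02, res.beta[0] + 0.02, step)
    b2 = np.arange(res.beta[1] - 0.02, res.beta[1] + 0.02, step)
    vals = np.array([[obj.value(np.array([a, b])) for b in b2] for a in b1])
    i, j = np.unravel_index(np.argmin(vals), vals.shape)
    assert abs(b1[i] - res.beta[0]) <= 2 * step
    assert abs(b2[j] - res.beta[1]) <= 2 * step
    assert obj.value(res.beta) <= vals.min() + 1e-10


def test_mm_recovers_model1_without_contamination(lpre_model):
    errs = []
    for seed in range(5):
        data, _ = rg.simulate_dataset(rg.model1_config(seed=seed),
                                      model=lpre_model)
        obj = GammaObjective(lpre_model, data, 0.5)
        res = fit_mm(obj)
        errs.append(float(np.sum((res.beta - 1.0) ** 2)))
        b_mle = fit_gre_mle("lpre", data)
        mse_mle = float(np.sum((b_mle - 1.0) ** 2))
        assert errs[-1] < 10 * max(mse_mle, 1e-3)
    assert np.median(errs) < 0.05


def test_mm_stationarity_scales_with_tolerance(lpre_model, clean_data):
    obj = GammaObjective(lpre_model, clean_data, 0.5)
    loose = fit_mm(obj, tol=1e-6)
    tight = fit_mm(obj, tol=1e-12)
    assert tight.final_grad_norm < loose.final_grad_norm + 1e-12
    # MM's linear rate leaves grad ~ sqrt(tol * curvature)
    assert tight.final_grad_norm <= 100 * math.sqrt(1e-12) * 1e3


def test_mm_intercept_equivariance(lpre_model, rng):
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    y = np.exp(X @ np.array([0.5, 1.0, -0.5])) * rng.uniform(0.5, 2, n)
    d1 = RegressionData(X, y, intercept_column=0)
    sigma = 4.0
    d2 = d1.scaled_response(sigma)
    r1 = fit_mm(GammaObjective(lpre_model, d1, 0.5))
    r2 = fit_mm(GammaObjective(lpre_model, d2, 0.5))
    shift = np.array([math.log(sigma), 0.0, 0.0])
    np.testing.assert_allclose(r2.beta, r1.beta + shift, atol=1e-8)


def test_mm_refuses_rank_deficient_design(lpre_model):
    X = np.column_stack([np.ones(12), np.ones(12)])
    data = RegressionData(X, np.full(12, 2.0))
    obj = GammaObjective(lpre_model, data, 0.5)
    with pytest.raises(np.linalg.LinAlgError, match="rank"):
        fit_mm(obj)


def test_mm_deterministic_given_start(lpre_model, contaminated_data):
    obj = GammaObjective(lpre_model, contaminated_data, 0.5)
    r1 = fit_mm(obj, beta0=np.zeros(3))
    r2 = fit_mm(obj, beta0=np.zeros(3))
    np.testing.assert_array_equal(r1.beta, r2.beta)
    np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)


# -------------------------------------------------------------- fit_hybrid
def test_hybrid_never_worse_than_mm(lpre_model):
    for seed in range(5):
        cfg = rg.model1_config(n=100, delta=0.1, seed=seed)
        data, _ = rg.simulate_dataset(cfg, model=lpre_model)
        obj = GammaObjective(lpre_model, data, 0.5)
        mm = fit_mm(obj)
        hy = fit_hybrid(obj)
        assert hy.objective <= mm.objective + 1e-8


def test_hybrid_agrees_with_mm_on_clean_data(lpre_model, clean_data):
    obj = GammaObjective(lpre_model, clean_data, 0.5)
    mm = fit_mm(obj, tol=1e-12)
    hy = fit_hybrid(obj, tol=1e-12)
    np.testing.assert_allclose(hy.beta, mm.beta, atol=1e-5)


def test_hybrid_stationarity(lpre_model, clean_data):
    """The BFGS phase drives the gradient to its gtol (= tol), far below
    what the objective-change rule of pure MM guarantees."""
    obj = GammaObjective(lpre_model, clean_data, 0.5)
    tol = 1e-8
    hy = fit_hybrid(obj, tol=tol)
    assert not hy.fallback
    assert hy.final_grad_norm <= 10 * tol * math.sqrt(clean_data.p) * 10


def test_hybrid_survives_bad_start(lpre_model, contaminated_data):
    obj = GammaObjective(lpre_model, contaminated_data, 0.5)
    res = fit_hybrid(obj, beta0=np.array([30.0, -30.0, 30.0]))
    assert np.all(np.isfinite(res.beta))
    assert np.all(np.diff(res.objective_trace) <= 1e-12)
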