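import math

import numpy as np
import pytest

import relgamma as rg
import relgamma.inference as inf
from relgamma import (RegressionData, constants_by_quadrature,
                      empirical_moments, lpre_constants_closed_form,
                      sandwich_covariance, wald_interval, z_standardize)


# ------------------------------------------------------ asymptotic constants
@pytest.mark.parametrize("gamma", [0.1, 0.5, 1.0])
def test_lpre_closed_form_matches_quadrature(lpre_model, gamma):
    cf = lpre_constants_closed_form(gamma)
    q = constants_by_quadrature(lpre_model, gamma)
    assert cf.C == pytest.approx(q.C, rel=1e-6)
    assert cf.C1 == pytest.approx(q.C1, rel=1e-6)
    assert cf.C2 == pytest.approx(q.C2, rel=1e-6)
    assert cf.C2_half == pytest.approx(q.C2_half, rel=1e-6)


@pytest.mark.parametrize("gamma", [0.1, 0.5, 1.0])
def test_c1_identity_both_losses(lpre_model, lsre_model, gamma):
    """C1 = -C/(1+gamma): integration by parts for any density with
    vanishing tails (AsymptoticConstants enforces it at 1e-7)."""
    for model in (lpre_model, lsre_model):
        c = constants_by_quadrature(model, gamma)
        assert c.C1 == pytest.approx(-c.C / (1.0 + gamma), rel=1e-7)


def test_constants_gamma_to_zero_limits(lpre_model):
    c = lpre_constants_closed_form(1e-6)
    assert c.C == pytest.approx(1.0, abs=1e-4)
    assert c.C1 == pytest.approx(-1.0, abs=1e-4)
    # C2 -> int u^2 h, the Fisher scalar of the noise
    m = inf.constants_by_quadrature(lpre_model, 1e-6)
    assert c.C2 == pytest.approx(m.C2, rel=1e-5)
    assert c.C2 > 0 and m.C2_half > 0


def test_misgrouped_c1_fails_identity():
    """The flattened closed-form text admits a reading with (1+gamma)
    multiplying instead of dividing; the identity rejects it."""
    g = 0.5
    c = lpre_constants_closed_form(g)
    wrong_c1 = -c.C * (1.0 + g)
    assert not math.isclose(wrong_c1, -c.C / (1.0 + g), rel_tol=1e-7)
    with pytest.raises(AssertionError):
        inf.AsymptoticConstants(gamma=g, C=c.C, C1=wrong_c1, C2=c.C2,
                                C2_half=c.C2_half)


# --------------------------------------------------------- empirical moments
def test_moments_at_gamma_zero_are_design_moments(rng):
    X = rng.normal(size=(40, 3))
    data = RegressionData(X, np.ones(40))
    m = empirical_moments(data, rng.normal(size=3), 0.0)
    assert m.pi0 == pytest.approx(1.0)
    np.testing.assert_allclose(m.pi1, X.mean(axis=0), rtol=1e-12)
    np.testing.assert_allclose(m.pi2, X.T @ X / 40, rtol=1e-12)


def test_moments_ones_column_closed_form():
    data = RegressionData(np.ones((25, 1)), np.full(25, 2.0))
    beta = np.array([0.7])
    m = empirical_moments(data, beta, 0.4)
    assert m.pi0 == pytest.approx(math.exp(-0.4 * 0.7), rel=1e-12)


def test_moments_consistency_gaussian_design(rng):
    """LLN: empirical moments at n = 1e5 approach the analytic Gaussian
    values E[x^(k) exp(-gamma x'beta)] for x ~ N(0, I)."""
    n, p, gamma = 100_000, 3, 0.5
    beta = np.array([1.0, 1.0, 1.0])
    X = rng.standard_normal((n, p))
    data = RegressionData(X, np.ones(n))
    m = empirical_moments(data, beta, gamma)
    a = -gamma * beta
    m0 = math.exp(0.5 * float(a @ a))
    m1 = m0 * a
    m2 = m0 * (np.eye(p) + np.outer(a, a))
    assert m.pi0 == pytest.approx(m0, rel=0.02)
    np.testing.assert_allclose(m.pi1, m1, atol=0.03 * m0)
    np.testing.assert_allclose(m.pi2, m2, atol=0.06 * m0)


# ------------------------------------------------------------------ sandwich
def test_sandwich_symmetric_and_psd(lpre_model, contaminated_data):
    b = rg.fit_relative_error(contaminated_data, gamma=0.5,
                              method="hybrid").beta
    cov = sandwich_covariance(lpre_model, contaminated_data, b, 0.5)
    S = cov.sandwich
    assert np.abs(S - S.T).max() <= 1e-12
    assert np.linalg.eigvalsh(S).min() >= -1e-12
    assert np.all(cov.se > 0)
    assert cov.H_prime > 0


def test_sandwich_small_gamma_is_inverse_fisher(lpre_model, clean_data):
    b = rg.fit_gre_mle("lpre", clean_data)
    cov = sandwich_covariance(lpre_model, clean_data, b, 1e-6)
    mom0 = empirical_moments(clean_data, b, 0.0)
    I0 = inf.fisher_information(lpre_model, mom0)
    expected = np.linalg.inv(I0) / clean_data.n
    np.testing.assert_allclose(cov.sandwich, expected, rtol=1e-4)


def test_delta_j_limits_at_tiny_gamma(lpre_model, clean_data):
    b = rg.fit_gre_mle("lpre", clean_data)
    g = 1e-5
    cg = inf.get_constants(lpre_model, g)
    c2g = inf.get_constants(lpre_model, 2 * g)
    mg = empirical_moments(clean_data, b, g)
    m2g = empirical_moments(clean_data, b, 2 * g)
    D = inf.delta_matrix(cg, c2g, mg, m2g)
    J = inf.j_matrix(cg, mg)
    I0 = inf.fisher_information(lpre_model,
                                empirical_moments(clean_data, b, 0.0))
    tol = 1e-4 * (1.0 + np.abs(I0))
    assert np.all(np.abs(D - I0) <= tol)
    assert np.all(np.abs(J - I0) <= tol)


def test_delta_matches_monte_carlo_gradient_covariance(lpre_model):
    """The parenthesization validator: Delta (paper-scaled by
    (C Pi0)^2 * C^2) must equal the covariance of the gamma-likelihood
    gradient at beta0, estimated by Monte Carlo."""
    gamma, p, n, R = 0.5, 2, 1000, 3000
    kap = gamma / (1.0 + gamma)
    beta0 = np.array([1.0, -0.5])
    rng = np.random.default_rng(2024)
    grads = np.empty((R, p))
    block = 250
    for r0 in range(0, R, block):
        X = rng.standard_normal((block, n, p))
        eps = rg.sample_noise(lpre_model, block * n, rng).reshape(block, n)
        t = np.exp(X @ beta0)
        fg = t**-gamma * np.exp(gamma * lpre_model.log_h(eps))
        u = 1.0 / eps - eps
        num = (fg[..., None] * (-u[..., None] * X)).mean(1)
        den = fg.mean(1)
        tg = t**-gamma
        grads[r0:r0 + block] = (-num / den[:, None]
                                - kap * (tg[..., None] * X).mean(1)
                                / tg.mean(1)[:, None])
    emp = n * np.cov(grads.T)
    cg = inf.get_constants(lpre_model, gamma)
    c2g = inf.get_constants(lpre_model, 2 * gamma)
    # population moments for N(0, I) predictors
    a = -gamma * beta0
    m0 = math.exp(0.5 * float(a @ a))
    mg = inf.MomentEstimates(gamma, m0, m0 * a,
                             m0 * (np.eye(p) + np.outer(a, a)), n)
    a2 = -2 * gamma * beta0
    m02 = math.exp(0.5 * float(a2 @ a2))
    m2g = inf.MomentEstimates(2 * gamma, m02, m02 * a2,
                              m02 * (np.eye(p) + np.outer(a2, a2)), n)
    D = inf.delta_matrix(cg, c2g, mg, m2g)
    # Delta is stated on the paper scale: (C^2 Pi0^2)^2 times the variance
    # of the gradient of the (1/n)-normalized objective
    scale = (cg.C * m0) ** 4
    np.testing.assert_allclose(scale * emp, D, rtol=0.25, atol=0.02)


# ------------------------------------------------------------ wald intervals
def _dummy_result(se):
    se = np.asarray(se, float)
    p = se.size
    return inf.CovarianceResult(gamma=0.5, Delta=np.eye(p), J=np.eye(p),
                                sandwich=np.diag(se**2), se=se, n=100,
                                H_prime=1.0, H_second=np.zeros(p))


def test_wald_degenerate_interval_at_zero_se():
    res = _dummy_result([0.0, 1.0])
    beta = np.array([2.0, 3.0])
    ci = wald_interval(res, beta, level=0.95)
    assert ci[0, 0] == ci[0, 1] == 2.0
    assert ci[1, 0] < 3.0 < ci[1, 1]


def test_wald_interval_widens_with_level():
    res = _dummy_result([1.0])
    beta = np.array([0.0])
    widths = [np.diff(wald_interval(res, beta, level=l)[0])[0]
              for l in (0.5, 0.8, 0.95, 0.99)]
    assert all(a < b for a, b in zip(widths, widths[1:]))


def test_wald_rejects_bad_level():
    with pytest.raises(ValueError):
        wald_interval(_dummy_result([1.0]), np.zeros(1), level=1.0)


def test_z_standardize_zero_at_truth():
    res = _dummy_result([1.0, 2.0])
    b = np.array([0.3, -0.2])
    np.testing.assert_allclose(z_standardize(b, b, res), np.zeros(2))
    z = z_standardize(b + np.array([1.0, 2.0]), b, res)
    np.testing.assert_allclose(z, np.ones(2))


def test_z_standardize_rejects_zero_variance():
    with pytest.raises(ValueError):
        z_standardize(np.ones(1), np.zeros(1), _dummy_result([0.0]))
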