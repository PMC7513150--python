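"""The negative gamma-likelihood for multiplicative regression.

For a model density ``f(y|x; beta) = h(y e^{-x'beta}) e^{-x'beta}`` and a
robustness parameter ``gamma > 0``, the negative gamma-(partial-)likelihood
is

    L_{gamma,n}(beta) = -(1/gamma) log( (1/n) sum_i f(y_i|x_i; beta)^gamma )
                        + 1/(1+gamma) log( (1/n) sum_i t_i^{-gamma} C(gamma, h) ),

with ``t_i = exp(x_i' beta)`` and ``C(gamma, h) = int h^{1+gamma}``.  As
``gamma -> 0`` this tends (up to constants) to the scaled negative
log-likelihood, i.e. the plain GRE criterion; larger ``gamma`` discounts
observations with low model density, which is what buys robustness: the
per-observation estimating contribution ``f^gamma s`` vanishes as the
response tends to 0 or infinity (the redescending property).

Internally the objective is evaluated through the split

    L = ell1 + ell2 + C0,
    ell1 = -(1/gamma) log sum_i f_i^gamma,
    ell2 = 1/(1+gamma) log sum_i t_i^{-gamma},
    C0   = (1/gamma - 1/(1+gamma)) log n + log C(gamma, h) / (1+gamma),

with every sum of exponentials stabilized by max subtraction, so the value
is finite for any finite ``beta``.  The ``1/n`` normalization is retained
so reported objective values are comparable across sample sizes.
"""

from __future__ import annotations

import math
import numpy as np
from scipy.special import kv, logsumexp

from .data import RegressionData
from .noise import K0_2, NoiseModel, make_noise_model

__all__ = ["GammaObjective", "c_gamma_h", "lpre_c_gamma_closed_form",
           "score_s", "psi_contribution"]


def lpre_c_gamma_closed_form(gamma: float) -> float:
    """``C(gamma, h) = K_gamma(2+2 gamma) / (2**gamma K_0(2)**(1+gamma))``
    for the LPRE noise density (an index-0 generalized inverse Gaussian)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(kv(gamma, 2.0 + 2.0 * gamma)
                 / (2.0**gamma * K0_2 ** (1.0 + gamma)))


def c_gamma_h(model: NoiseModel, gamma: float, cross_check: bool = True
              ) -> float:
    """``C(gamma, h) = int_0^inf h(v)**(1+gamma) dv``.

    Uses the Bessel closed form for LPRE (asserted against quadrature when
    ``cross_check``), quadrature otherwise.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if model.closed_form and model.loss.name == "lpre":
        closed = lpre_c_gamma_closed_form(gamma)
        if cross_check:
            quad = model.integral_h_power(1.0 + gamma)
            if not math.isclose(closed, quad, rel_tol=1e-6):
                raise AssertionError(
                    f"LPRE C(gamma,h) closed form {closed!r} disagrees with "
                    f"quadrature {quad!r} at gamma={gamma}")
        return closed
    val = model.integral_h_power(1.0 + gamma)
    if not np.isfinite(val):
        raise ValueError(f"int h**(1+gamma) diverges at gamma={gamma}")
    return val


def score_s(model: NoiseModel, y, x, beta) -> np.ndarray:
    """Score ``s(y|x;beta) = d log f / d beta = -u_h(eps) x`` with
    ``eps = y exp(-x'beta)``."""
    y = float(y)
    if y <= 0:
        raise ValueError("response y must be strictly positive")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    log_eps = math.log(y) - float(x @ beta)
    return -float(model.u_h_from_log(log_eps)) * x


def psi_contribution(model: NoiseModel, y, x, beta, gamma: float
                     ) -> np.ndarray:
    """The y-dependent part of the estimating function,
    ``f(y|x;beta)**gamma * s(y|x;beta)``.

    Bounded by ``const * h(eps)**gamma |u_h(eps)|`` which vanishes as
    ``y -> 0`` or ``y -> inf`` — the redescending property.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    y = float(y)
    if y <= 0:
        raise ValueError("response y must be strictly positive")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    xb = float(x @ beta)
    log_eps = math.log(y) - xb
    logf = -xb + float(model.log_h_from_log(log_eps))
    u = float(model.u_h_from_log(log_eps))
    # f^gamma * (-u) may be 0 * inf in the far tails; the density power wins
    with np.errstate(over="ignore"):
        mag = math.exp(gamma * logf) if gamma * logf < 700 else math.inf
    val = -mag * u
    if not math.isfinite(val):
        # log-scale product: sign(-u) * exp(gamma log f + log|u|)
        val = -math.copysign(
            math.exp(min(gamma * logf + math.log(abs(u)), 700.0)), u
        ) if u != 0 else 0.0
    return val * x


class GammaObjective:
    """Negative gamma-likelihood bound to a (noise model, data, gamma)
    triple, with cached constants.

    Parameters
    ----------
    model : NoiseModel or str
        Noise density (a loss name is accepted and promoted).
    data : RegressionData
    gamma : float
        Robustness tuning parameter, ``gamma > 0``.
    """

    def __init__(self, model, data: RegressionData, gamma: float):
        if isinstance(model, str):
            model = make_noise_model(model)
        if gamma <= 0:
            raise ValueError("gamma must be positive; use fit_gre_mle for "
                             "the gamma -> 0 (maximum likelihood) limit")
        self.model = model
        self.data = data
        self.gamma = float(gamma)
        self.C = c_gamma_h(model, self.gamma)
        self._logy = np.log(data.y)
        self._kappa = self.gamma / (1.0 + self.gamma)

    # -- pieces ------------------------------------------------------------
    @property
    def C0(self) -> float:
        n = self.data.n
        g = self.gamma
        return ((1.0 / g - 1.0 / (1.0 + g)) * math.log(n)
                + math.log(self.C) / (1.0 + g))

    def log_f(self, beta) -> np.ndarray:
        """Vector of ``log f(y_i | x_i; beta)``."""
        beta = np.asarray(beta, dtype=float).ravel()
        xb = self.data.X @ beta
        return -xb + self.model.log_h_from_log(self._logy - xb)

    def ell1(self, beta) -> float:
        return float(-logsumexp(self.gamma * self.log_f(beta)) / self.gamma)

    def ell2(self, beta) -> float:
        beta = np.asarray(beta, dtype=float).ravel()
        return float(logsumexp(-self.gamma * (self.data.X @ beta))
                     / (1.0 + self.gamma))

    # -- objective ---------------------------------------------------------
    def value(self, beta) -> float:
        """Stabilized evaluation via the ell1 + ell2 + C0 split."""
        return self.ell1(beta) + self.ell2(beta) + self.C0

    def value_direct(self, beta) -> float:
        """Direct (unstabilized) evaluation of the defining expression;
        kept as an independent cross-check of :meth:`value`."""
        beta = np.asarray(beta, dtype=float).ravel()
        g = self.gamma
        f = np.exp(self.log_f(beta))
        t = np.exp(self.data.X @ beta)
        return float(-math.log(np.mean(f**g)) / g
                     + math.log(np.mean(t**-g) * self.C) / (1.0 + g))

    # -- per-observation ingredients ---------------------------------------
    def weights(self, beta) -> np.ndarray:
        """Density-power weights ``w_i = f_i^gamma / sum_j f_j^gamma``
        (log-sum-exp stabilized; sums to one)."""
        lf = self.gamma * self.log_f(beta)
        m = lf.max()
        if not np.isfinite(m):
            raise FloatingPointError(
                "all model densities underflow at this beta; the start "
                "point is pathological for this data set")
        w = np.exp(lf - m)
        return w / w.sum()

    def softmax_pi(self, beta) -> np.ndarray:
        """``pi_i = exp(-gamma x_i'beta) / sum_j exp(-gamma x_j'beta)``."""
        beta = np.asarray(beta, dtype=float).ravel()
        th = -self.gamma * (self.data.X @ beta)
        th -= th.max()
        e = np.exp(th)
        return e / e.sum()

    def gradient(self, beta) -> np.ndarray:
        """Exact gradient of :meth:`value`:
        ``X' (w * u_h(eps)) - gamma/(1+gamma) X' pi``."""
        beta = np.asarray(beta, dtype=float).ravel()
        X = self.data.X
        xb = X @ beta
        u = self.model.u_h_from_log(self._logy - xb)
        w = self.weights(beta)
        pi = self.softmax_pi(beta)
        return X.T @ (w * u) - self._kappa * (X.T @ pi)

    def __repr__(self):
        return (f"GammaObjective(loss={self.model.loss.name!r}, "
                f"gamma={self.gamma}, n={self.data.n}, p={self.data.p})")
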