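"""Monotone MM optimizer for the negative gamma-likelihood.

The objective splits as ``ell1 + ell2`` (plus constants).  Each piece gets
a convex surrogate touching it at the current iterate ``beta_t``:

* ``ell1`` — Jensen majorizer: with density-power weights ``w_i(t)``,
  ``elltilde1(beta | beta_t) = -sum_i w_i(t) log f(y_i|x_i; beta) + C1``,
  a weighted GRE criterion (convex whenever the loss is convex).
* ``ell2`` — quadratic bound majorizer: the log-sum-exp Hessian is
  dominated by ``B = (I - 11'/n) / 2``, giving
  ``elltilde2(beta | beta_t) = gamma^2/(2(1+gamma)) beta' M beta
  - gamma/(1+gamma) beta' (X'pi(t) + gamma M beta_t) + C2`` with
  ``M = X'BX = (X'X - n xbar xbar')/2`` (never materializing B).

Minimizing the surrogate sum at each step guarantees a nonincreasing
objective trace.  A hybrid variant follows a few MM steps with BFGS on the
objective itself, falling back to pure MM if BFGS misbehaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .gre import _rank_check, fit_gre_mle
from .objective import GammaObjective

__all__ = ["FitResult", "compute_weights", "majorizer1", "majorizer2",
           "inner_minimize", "fit_mm", "fit_hybrid"]


@dataclass
class FitResult:
    """Outcome of a gamma-likelihood (or GRE) fit."""

    beta: np.ndarray
    gamma: float
    converged: bool
    n_iterations: int
    objective_trace: np.ndarray
    final_grad_norm: float
    method: str = "mm"
    #: hybrid only: True when the BFGS phase was rejected and pure MM used
    fallback: bool = False

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def compute_weights(obj: GammaObjective, beta_t) -> np.ndarray:
    """Density-power weights ``w_i = f_i^gamma / sum_j f_j^gamma`` at the
    current iterate (nonnegative, sum to one)."""
    return obj.weights(beta_t)


def _xtbx(X: np.ndarray) -> np.ndarray:
    """``X'BX`` with ``B = (I - 11'/n)/2``, i.e. half the centered Gram
    matrix; computed without forming B."""
    n = X.shape[0]
    xbar = X.mean(axis=0)
    return 0.5 * (X.T @ X - n * np.outer(xbar, xbar))


def majorizer1(obj: GammaObjective, beta, beta_t) -> float:
    """Jensen surrogate for ``ell1`` (dominates it, touches at beta_t)."""
    w = obj.weights(beta_t)
    # C = (1/gamma) sum w log w  restores tangency
    c = float(np.sum(w * np.log(np.clip(w, 1e-300, None)))) / obj.gamma
    return float(-np.sum(w * obj.log_f(beta))) + c


def majorizer2(obj: GammaObjective, beta, beta_t) -> float:
    """Quadratic bound surrogate for ``ell2`` (dominates it, touches at
    beta_t); its Hessian ``gamma^2/(1+gamma) X'BX`` is PSD."""
    beta = np.asarray(beta, dtype=float).ravel()
    beta_t = np.asarray(beta_t, dtype=float).ravel()
    g = obj.gamma
    X = obj.data.X
    M = _xtbx(X)
    pi = obj.softmax_pi(beta_t)
    lin = X.T @ pi + g * (M @ beta_t)

    def core(b):
        return (g * g / (2.0 * (1.0 + g)) * float(b @ M @ b)
                - g / (1.0 + g) * float(b @ lin))

    # beta-free constant fixed by tangency at beta_t
    c = obj.ell2(beta_t) - core(beta_t)
    return core(beta) + c


def _surrogate_pieces(obj: GammaObjective, beta_t):
    """Precompute everything the inner Newton needs."""
    X, y = obj.data.X, obj.data.y
    g = obj.gamma
    w = obj.weights(beta_t)
    M = _xtbx(X)
    pi = obj.softmax_pi(beta_t)
    lin = X.T @ pi + g * (M @ beta_t)
    kap = g / (1.0 + g)
    logy = np.log(y)
    model = obj.model

    def value(b):
        # -sum w log f + quadratic part (constants dropped; only
        # differences matter inside the line search)
        xb = X @ b
        lf = -xb + model.log_h_from_log(logy - xb)
        return (-float(w @ lf)
                + g * kap / 2.0 * float(b @ M @ b) - kap * float(b @ lin))

    def grad(b):
        xb = X @ b
        u = model.u_h_from_log(logy - xb)
        return X.T @ (w * u) + g * kap * (M @ b) - kap * lin

    def hess(b):
        xb = X @ b
        eps = np.exp(np.clip(logy - xb, -350.0, 350.0))
        curv = -eps * model.du_h(eps)  # = eps rho' + eps^2 rho'' >= 0 convex
        return (X * (w * curv)[:, None]).T @ X + g * kap * M

    return value, grad, hess


def inner_minimize(obj: GammaObjective, beta_t, tol: float = 1e-10,
                   max_iter: int = 100) -> np.ndarray:
    """Minimize the convex surrogate ``elltilde1 + elltilde2`` at ``beta_t``
    by damped Newton (ridge-damped retry on a singular Hessian)."""
    value, grad, hess = _surrogate_pieces(obj, beta_t)
    b = np.asarray(beta_t, dtype=float).ravel().copy()
    val = value(b)
    for _ in range(max_iter):
        gvec = grad(b)
        if np.linalg.norm(gvec) <= tol:
            break
        H = hess(b)
        try:
            step = np.linalg.solve(H, -gvec)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            ridge = 1e-8 * max(1.0, float(np.trace(H)) / H.shape[0])
            try:
                step = np.linalg.solve(H + ridge * np.eye(H.shape[0]), -gvec)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "surrogate Hessian singular even after ridge damping; "
                    "check the design matrix") from exc
        t = 1.0
        for _ in range(60):
            cand = b + t * step
            vc = value(cand)
            if vc <= val + 1e-4 * t * float(gvec @ step):
                b, val = cand, vc
                break
            t *= 0.5
        else:
            break
    return b


def _default_start(obj: GammaObjective) -> np.ndarray:
    """Convex GRE minimizer when available, else least squares on log y."""
    try:
        return fit_gre_mle(obj.model.loss, obj.data)
    except (ValueError, np.linalg.LinAlgError, RuntimeError):
        return np.linalg.lstsq(obj.data.X, np.log(obj.data.y), rcond=None)[0]


def fit_mm(obj: GammaObjective, beta0=None, max_iter: int = 500,
           tol: float = 1e-8, inner_tol: float = 1e-10) -> FitResult:
    """MM iteration: weight update + surrogate minimization until the
    relative objective change falls below ``tol``.

    The returned trace is monotone nonincreasing by construction; a fit
    that exhausts ``max_iter`` is returned with ``converged=False``.
    """
    _rank_check(obj.data.X)
    beta = (_default_start(obj) if beta0 is None
            else np.asarray(beta0, dtype=float).ravel().copy())
    trace = [obj.value(beta)]
    converged = False
    for it in range(max_iter):
        beta_new = inner_minimize(obj, beta, tol=inner_tol)
        val_new = obj.value(beta_new)
        # surrogate minimization cannot increase the objective; numerical
        # noise at stationarity is clipped by the convergence test
        if val_new > trace[-1]:
            beta_new, val_new = beta, trace[-1]
        trace.append(val_new)
        moved = abs(trace[-2] - val_new) <= tol * (1.0 + abs(trace[-2]))
        beta = beta_new
        if moved:
            converged = True
            break
    gnorm = float(np.linalg.norm(obj.gradient(beta)))
    return FitResult(beta=beta, gamma=obj.gamma, converged=converged,
                     n_iterations=len(trace) - 1,
                     objective_trace=np.asarray(trace),
                     final_grad_norm=gnorm, method="mm")


def fit_hybrid(obj: GammaObjective, beta0=None, mm_iters: int = 10,
               tol: float = 1e-8, max_iter: int = 500) -> FitResult:
    """A few MM steps for stability, then BFGS on the objective for speed.

    If the BFGS phase fails or ends above the MM iterate's objective, the
    result falls back to a full MM run (flagged via ``fallback``).
    """
    warm = fit_mm(obj, beta0=beta0, max_iter=mm_iters, tol=tol)
    try:
        res = optimize.minimize(obj.value, warm.beta, jac=obj.gradient,
                                method="BFGS",
                                options={"gtol": tol, "maxiter": 500})
        ok = np.all(np.isfinite(res.x)) and np.isfinite(res.fun) \
            and res.fun <= warm.objective + 1e-12
    except (FloatingPointError, ValueError, OverflowError):
        res, ok = None, False
    if ok:
        trace = np.append(warm.objective_trace, res.fun)
        return FitResult(beta=res.x, gamma=obj.gamma,
                         converged=True, n_iterations=warm.n_iterations
                         + int(res.nit),
                         objective_trace=trace,
                         final_grad_norm=float(np.linalg.norm(
                             obj.gradient(res.x))),
                         method="hybrid")
    full = fit_mm(obj, beta0=warm.beta, max_iter=max_iter, tol=tol)
    full.method = "hybrid"
    full.fallback = True
    return full
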