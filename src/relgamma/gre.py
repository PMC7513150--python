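"""GRE criterion evaluation and its (non-robust) minimizer.

``gre_loss_value`` is the classical relative-error objective
``G(beta) = sum_i g(|y_i-t_i|/y_i, |y_i-t_i|/t_i)`` with
``t_i = exp(x_i' beta)``; for the loss-induced noise density this equals
``sum_i rho(y_i / t_i)`` and its minimizer is the exact MLE.  For LPRE and
LSRE the objective is smooth and convex, so a damped Newton iteration
converges globally.
"""

from __future__ import annotations

import numpy as np

from .data import RegressionData
from .losses import GRELoss, gre_loss

__all__ = ["gre_loss_value", "fit_gre_mle"]


def _as_loss(loss) -> GRELoss:
    return gre_loss(loss) if isinstance(loss, str) else loss


def gre_loss_value(loss, data: RegressionData, beta) -> float:
    """``sum_i rho(y_i * exp(-x_i' beta))`` — the GRE criterion."""
    loss = _as_loss(loss)
    beta = np.asarray(beta, dtype=float).ravel()
    eps = data.y * np.exp(-data.X @ beta)
    return float(np.sum(loss.rho(eps)))


def _rank_check(X: np.ndarray):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; remove collinear columns "
            "before fitting (no silent regularization is applied)")


def fit_gre_mle(loss, data: RegressionData, tol: float = 1e-10,
                max_iter: int = 200, beta0=None) -> np.ndarray:
    """Minimize the GRE criterion by damped Newton with backtracking.

    Requires a convex loss (LPRE/LSRE, or a custom loss flagged convex).
    Returns the coefficient vector with gradient norm at most ``tol``.
    Start is least squares on ``(X, log y)`` unless ``beta0`` is given.
    """
    loss = _as_loss(loss)
    if not loss.convex:
        raise ValueError(f"loss {loss.name!r} is not flagged convex; "
                         "fit_gre_mle requires a convex GRE criterion")
    X, y = data.X, data.y
    _rank_check(X)
    if beta0 is None:
        beta = np.linalg.lstsq(X, np.log(y), rcond=None)[0]
    else:
        beta = np.asarray(beta0, dtype=float).ravel().copy()

    def value(b):
        return float(np.sum(loss.rho(y * np.exp(-X @ b))))

    val = value(beta)
    for _ in range(max_iter):
        eps = y * np.exp(-X @ beta)
        # grad = sum rho'(eps) * (-eps) x = sum u(eps) x with u = -eps rho'
        u = -eps * loss.drho(eps)
        grad = X.T @ u
        gnorm = float(np.linalg.norm(grad))
        if gnorm <= tol:
            break
        # Hessian = sum (eps rho' + eps^2 rho'') x x'
        curv = eps * loss.drho(eps) + eps**2 * loss.d2rho(eps)
        H = (X * curv[:, None]).T @ X
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -grad, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            raise np.linalg.LinAlgError("Newton step failed (singular "
                                        "Hessian); check the design matrix")
        # backtracking line search on the convex objective
        t = 1.0
        for _ in range(60):
            cand = beta + t * step
            vc = value(cand)
            if vc <= val + 1e-4 * t * float(grad @ step):
                beta, val = cand, vc
                break
            t *= 0.5
        else:  # pragma: no cover - convexity makes this unreachable
            break
    else:
        eps = y * np.exp(-X @ beta)
        gnorm = float(np.linalg.norm(X.T @ (-eps * loss.drho(eps))))
        if gnorm > max(tol, 1e-6):
            raise RuntimeError(
                f"fit_gre_mle did not converge in {max_iter} iterations "
                f"(gradient norm {gnorm:.3e})")
    return beta
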