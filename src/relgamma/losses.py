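"""General relative error (GRE) losses.

A GRE criterion measures the discrepancy between a positive response ``y``
and a positive prediction ``t`` through the two relative errors
``a = |y - t| / y`` and ``b = |y - t| / t``, combined by a symmetric
bivariate function ``g(a, b) = g(b, a)``.  Writing the multiplicative
residual ``eps = y / t``, the per-observation loss is

    rho(eps) = g(|1 - 1/eps|, |1 - eps|),

which is zero at ``eps = 1`` and invariant under ``eps -> 1/eps``.  The two
workhorse criteria are

* LPRE (least product relative error): ``g(a, b) = a * b``, for which
  ``rho(eps) = eps + 1/eps - 2``;
* LSRE (least squared-sum relative error): ``g(a, b) = a**2 + b**2``.

Both are smooth and convex in the regression coefficients and admit a
proper likelihood (see :mod:`relgamma.noise`).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["GRELoss", "LPRE", "LSRE", "gre_loss", "custom_gre_loss"]


def _check_nonneg(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("GRE loss arguments must be nonnegative")
    return a, b


def _check_pos(eps):
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("multiplicative residual eps must be strictly positive")
    return eps


class GRELoss:
    """A symmetric GRE loss ``g`` with the derivatives of ``rho`` that the
    Newton steps need.

    Subclasses (or :func:`custom_gre_loss`) provide ``g`` and the partial
    derivatives of ``g``; ``rho`` and its first two derivatives follow by
    the chain rule.  Built-in LPRE/LSRE override ``rho`` analytically.
    """

    name = "custom"
    #: smooth and convex in beta (true for LPRE / LSRE)
    convex = False

    def g(self, a, b):  # pragma: no cover - abstract
        raise NotImplementedError

    def g_a(self, a, b):  # pragma: no cover - abstract
        raise NotImplementedError

    def g_b(self, a, b):  # pragma: no cover - abstract
        raise NotImplementedError

    def g_aa(self, a, b):  # pragma: no cover - abstract
        raise NotImplementedError

    def g_ab(self, a, b):  # pragma: no cover - abstract
        raise NotImplementedError

    def g_bb(self, a, b):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- rho and derivatives by chain rule ---------------------------------
    def rho(self, eps):
        eps = _check_pos(eps)
        return self.g(np.abs(1.0 - 1.0 / eps), np.abs(1.0 - eps))

    def drho(self, eps):
        """d rho / d eps.  Uses a = |1-1/eps|, b = |1-eps| with
        a' = s/eps**2, b' = s where s = sign(eps - 1)."""
        eps = _check_pos(eps)
        s = np.sign(eps - 1.0)
        a = np.abs(1.0 - 1.0 / eps)
        b = np.abs(1.0 - eps)
        return self.g_a(a, b) * s / eps**2 + self.g_b(a, b) * s

    def d2rho(self, eps):
        eps = _check_pos(eps)
        s = np.sign(eps - 1.0)
        a = np.abs(1.0 - 1.0 / eps)
        b = np.abs(1.0 - eps)
        da = s / eps**2
        db = s
        d2a = -2.0 * s / eps**3
        return (self.g_aa(a, b) * da**2 + 2.0 * self.g_ab(a, b) * da * db
                + self.g_bb(a, b) * db**2 + self.g_a(a, b) * d2a)

    def __repr__(self):
        return f"{type(self).__name__}(name={self.name!r})"


class _LPRELoss(GRELoss):
    """g(a, b) = a * b;  rho(eps) = eps + 1/eps - 2."""

    name = "lpre"
    convex = True

    def g(self, a, b):
        a, b = _check_nonneg(a, b)
        return a * b

    def g_a(self, a, b):
        return np.asarray(b, dtype=float)

    def g_b(self, a, b):
        return np.asarray(a, dtype=float)

    def g_aa(self, a, b):
        return np.zeros_like(np.asarray(a, dtype=float))

    def g_ab(self, a, b):
        return np.ones_like(np.asarray(a, dtype=float))

    def g_bb(self, a, b):
        return np.zeros_like(np.asarray(a, dtype=float))

    def rho(self, eps):
        eps = _check_pos(eps)
        return eps + 1.0 / eps - 2.0

    def drho(self, eps):
        eps = _check_pos(eps)
        return 1.0 - eps**-2

    def d2rho(self, eps):
        eps = _check_pos(eps)
        return 2.0 * eps**-3


class _LSRELoss(GRELoss):
    """g(a, b) = a**2 + b**2;  rho(eps) = (1-1/eps)**2 + (1-eps)**2."""

    name = "lsre"
    convex = True

    def g(self, a, b):
        a, b = _check_nonneg(a, b)
        return a**2 + b**2

    def g_a(self, a, b):
        return 2.0 * np.asarray(a, dtype=float)

    def g_b(self, a, b):
        return 2.0 * np.asarray(b, dtype=float)

    def g_aa(self, a, b):
        return np.full_like(np.asarray(a, dtype=float), 2.0)

    def g_ab(self, a, b):
        return np.zeros_like(np.asarray(a, dtype=float))

    def g_bb(self, a, b):
        return np.full_like(np.asarray(a, dtype=float), 2.0)

    def rho(self, eps):
        eps = _check_pos(eps)
        return (1.0 - 1.0 / eps) ** 2 + (1.0 - eps) ** 2

    def drho(self, eps):
        eps = _check_pos(eps)
        return 2.0 * (1.0 - 1.0 / eps) / eps**2 - 2.0 * (1.0 - eps)

    def d2rho(self, eps):
        eps = _check_pos(eps)
        return 2.0 + 6.0 * eps**-4 - 4.0 * eps**-3


class _CustomGRELoss(GRELoss):
    def __init__(self, g, g_a, g_b, g_aa, g_ab, g_bb, name="custom",
                 convex=False):
        self._g, self._ga, self._gb = g, g_a, g_b
        self._gaa, self._gab, self._gbb = g_aa, g_ab, g_bb
        self.name = name
        self.convex = convex
        # cheap sanity probes: symmetry and nonnegativity of g
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 5, 32)
        b = rng.uniform(0, 5, 32)
        ga, gb = np.asarray(g(a, b), float), np.asarray(g(b, a), float)
        if np.any(ga < -1e-12):
            raise ValueError("custom g must be nonnegative")
        if not np.allclose(ga, gb, rtol=1e-9, atol=1e-12):
            raise ValueError("custom g must be symmetric: g(a, b) == g(b, a)")

    def g(self, a, b):
        a, b = _check_nonneg(a, b)
        return np.asarray(self._g(a, b), dtype=float)

    def g_a(self, a, b):
        return np.asarray(self._ga(a, b), dtype=float)

    def g_b(self, a, b):
        return np.asarray(self._gb(a, b), dtype=float)

    def g_aa(self, a, b):
        return np.asarray(self._gaa(a, b), dtype=float)

    def g_ab(self, a, b):
        return np.asarray(self._gab(a, b), dtype=float)

    def g_bb(self, a, b):
        return np.asarray(self._gbb(a, b), dtype=float)


LPRE = _LPRELoss()
LSRE = _LSRELoss()
_BUILTIN = {"lpre": LPRE, "lsre": LSRE}


def gre_loss(name: str) -> GRELoss:
    """Return a built-in GRE loss by name (``"lpre"`` or ``"lsre"``)."""
    try:
        return _BUILTIN[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown GRE loss {name!r}; built-ins are {sorted(_BUILTIN)}"
        ) from None


def custom_gre_loss(g: Callable, g_a: Callable, g_b: Callable,
                    g_aa: Callable, g_ab: Callable, g_bb: Callable,
                    name: str = "custom", convex: bool = False) -> GRELoss:
    """Build a GRE loss from a user-supplied symmetric ``g`` and its first
    and second partial derivatives (all vectorized over ``a``, ``b``).

    Derivatives of ``rho`` are obtained by the chain rule; no symbolic
    differentiation is attempted.
    """
    return _CustomGRELoss(g, g_a, g_b, g_aa, g_ab, g_bb, name=name,
                          convex=convex)


def eval_g(loss: GRELoss, a, b):
    """Evaluate ``g(a, b)``; raises on negative arguments."""
    a, b = _check_nonneg(a, b)
    return loss.g(a, b)


def eval_rho(loss: GRELoss, eps):
    """Evaluate ``rho(eps) = g(|1-1/eps|, |1-eps|)`` for ``eps > 0``."""
    return loss.rho(eps)
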