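"""Closed-form proximal operators and penalty functions.

These are the scalar/vector building blocks shared by the sparse quantile
regression and CT reconstruction applications: the asymmetric quantile
(check) loss and its prox, soft thresholding, Euclidean ball projection,
and the log-type nonconvex sparsity penalty ``lam * sum_j beta*log(1+|x_j|/beta)``
split into a convex l1 part plus a smooth concave remainder.

Conventions: ``sign(0) = 0`` (numpy's convention); ``beta = +inf`` is a
distinct code path recovering the pure l1 quantities exactly, with no
overflow.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quantile_loss",
    "soft_threshold",
    "project_l2_ball",
    "prox_l1_ball",
    "prox_quantile",
    "log_penalty_value",
    "log_penalty_smooth_value",
    "log_penalty_smooth_grad",
]


def _check_quantile(q: float) -> None:
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile level q must lie in (0, 1), got {q}")


def quantile_loss(t, q: float):
    """Check loss ``l_q(t) = q*max(t,0) + (1-q)*max(-t,0)``.

    Convex and piecewise linear with a kink at 0; its minimizer over a
    sample is the q-th empirical quantile. Vectorized over ``t``.
    """
    _check_quantile(q)
    t = np.asarray(t, dtype=float)
    return q * np.maximum(t, 0.0) + (1.0 - q) * np.maximum(-t, 0.0)


def soft_threshold(v, tau):
    """Elementwise ``sign(v) * max(|v| - tau, 0)``, the prox of ``tau*|.|``."""
    v = np.asarray(v, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("soft_threshold requires tau >= 0 elementwise")
    return np.sign(v) * np.maximum(np.abs(v) - tau, 0.0)


def project_l2_ball(v, radius: float):
    """Euclidean projection of ``v`` onto the ball ``{x : ||x||_2 <= radius}``."""
    if not radius > 0:
        raise ValueError("radius must be positive")
    v = np.asarray(v, dtype=float)
    if np.isinf(radius):
        return v.copy()
    nrm = float(np.linalg.norm(v))
    if nrm <= radius:
        return v.copy()
    return v * (radius / nrm)


def prox_l1_ball(v, tau, radius: float = np.inf):
    """Prox of ``x -> sum_j tau_j |x_j| + indicator(||x||_2 <= radius)``.

    Computed as soft thresholding followed by ball projection; in this
    order the composition is the exact prox of the sum (the reverse order
    is not). With a nonuniform diagonal metric the thresholds ``tau_j``
    differ per coordinate; exactness of the finite-radius case requires a
    uniform metric, which is how both applications use it.
    """
    return project_l2_ball(soft_threshold(v, tau), radius)


def prox_quantile(v, w, q: float, a, rho):
    """Minimizer of ``a*l_q(w - y) + (rho/2)*(y - v)^2`` over scalar y.

    Vectorized over ``v`` and ``w`` (and ``a``, ``rho`` if arrays). The
    solution clips the movement of ``v`` toward ``w``: it equals ``w``
    when ``w - v`` lies in ``[-a(1-q)/rho, a*q/rho]``, else it stops at
    the corresponding endpoint.
    """
    _check_quantile(q)
    a = np.asarray(a, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(a < 0):
        raise ValueError("prox_quantile requires a >= 0")
    if np.any(rho <= 0):
        raise ValueError("prox_quantile requires rho > 0")
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    hi = a * q / rho
    lo = -a * (1.0 - q) / rho
    r = w - v
    return np.where(r > hi, v + hi, np.where(r < lo, v + lo, w))


def log_penalty_value(x, lam: float, beta: float) -> float:
    """Nonconvex sparsity penalty ``lam * sum_j beta*log(1 + |x_j|/beta)``.

    Equals ``lam*||x||_1`` in the limit ``beta -> +inf`` (handled exactly).
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    x = np.asarray(x, dtype=float)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if np.isinf(beta):
        return float(lam * np.sum(np.abs(x)))
    return float(lam * beta * np.sum(np.log1p(np.abs(x) / beta)))


def log_penalty_smooth_value(x, lam: float, beta: float) -> float:
    """Smooth concave part ``lam * sum_j (beta*log(1+|x_j|/beta) - |x_j|)``.

    This is the penalty minus its l1 majorant; it is twice differentiable
    (including at 0), nonpositive, and identically 0 for ``beta = +inf``.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    x = np.asarray(x, dtype=float)
    if np.isinf(beta):
        return 0.0
    ax = np.abs(x)
    return float(lam * np.sum(beta * np.log1p(ax / beta) - ax))


def log_penalty_smooth_grad(x, lam: float, beta: float):
    """Gradient of :func:`log_penalty_smooth_value`: ``-lam*x_j/(beta+|x_j|)``.

    Continuous everywhere (0 at the origin), bounded by ``lam`` in absolute
    value, with Hessian bounded below by ``-lam/beta`` per coordinate.
    """
    if not beta > 0:
        raise ValueError("beta must be positive")
    x = np.asarray(x, dtype=float)
    if np.isinf(beta):
        return np.zeros_like(x)
    return -lam * x / (beta + np.abs(x))
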