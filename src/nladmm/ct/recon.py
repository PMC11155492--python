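"""Spectral CT maximum-likelihood reconstruction via nonconvex ADMM.

The reconstruction solves ``min_x Loss(P x)`` by splitting ``P x = y``:
``f(x) == 0`` and ``g(y) = gc(y) + gd(y)`` with

    gc(y) = sum_{w,l} sum_i S_{wli} qexp(-sum_m mu_{mi} y_{lm})     (convex)
    gd(y) = -sum_{w,l} C_{wl} log( sum_i S_{wli} qexp(...) )        (concave
            on the nonpositive-exponent region)

where ``qexp`` replaces the exponential by its quadratic Taylor
continuation for positive arguments, bounding the curvature so negative
path lengths at early iterations cannot blow up the optimization. For any
nonnegative image the exponent arguments are nonpositive and the modified
loss equals the exact Poisson negative log-likelihood up to the constant
``sum log C!``.

The ADMM operators are Kronecker products ``A = P (x) I_nm``,
``Sigma = SigmaTilde (x) I_nm`` and
``Hf = Qf (x) I - A' Sigma A`` with the diagonal preconditioners
``(Qf)_kk = sigma * sum_l P_lk`` and ``SigmaTilde_ll = sigma * sum_k P_lk``;
they are never materialized — everything is applied per material column,
with vectorization pixel-major and the material index fastest so that
``(P (x) I) vec(x) = vec(P x)``. The x update is then closed-form and the
y update separates into one small strictly convex smooth problem per ray,
solved by damped Newton. With ``Hg = 0`` the step-size condition
``Hg >= hess gd`` is guaranteed only where all exponent arguments are
nonpositive; a warning is surfaced if an iterate leaves that region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp

from ..core import LinearMap, RunResult, SplitProblem, StepConfig, run_admm
from .forward import AttenuationTable, SpectralModel, path_exponents, window_intensities

__all__ = [
    "qexp",
    "qexp_d1",
    "qexp_d2",
    "ct_loss",
    "ct_grad_gc",
    "ct_grad_gd",
    "Preconditioners",
    "build_preconditioners",
    "ct_x_update",
    "ct_y_update",
    "CtReconConfig",
    "NewtonError",
    "run_ct_recon",
    "rsc_alpha_series",
    "fosp_gradient_ratio",
    "PositiveExponentWarning",
]


class NewtonError(RuntimeError):
    """A per-ray Newton solve failed to reach its gradient tolerance."""


class PositiveExponentWarning(UserWarning):
    """An iterate produced positive exponent arguments (negative path lengths)."""


# ---------------------------------------------------------------------------
# qexp: exp with a quadratic continuation for positive arguments
# ---------------------------------------------------------------------------


def qexp(t):
    """``exp(t)`` for t <= 0, ``1 + t + t^2/2`` for t >= 0 (C^2 at 0)."""
    t = np.asarray(t, dtype=float)
    return np.where(t <= 0, np.exp(np.minimum(t, 0.0)), 1.0 + t + 0.5 * t * t)


def qexp_d1(t):
    """First derivative: ``exp(t)`` for t <= 0, ``1 + t`` for t >= 0."""
    t = np.asarray(t, dtype=float)
    return np.where(t <= 0, np.exp(np.minimum(t, 0.0)), 1.0 + t)


def qexp_d2(t):
    """Second derivative: ``exp(t)`` for t <= 0, ``1`` for t >= 0."""
    t = np.asarray(t, dtype=float)
    return np.where(t <= 0, np.exp(np.minimum(t, 0.0)), 1.0)


# ---------------------------------------------------------------------------
# Loss and gradients
# ---------------------------------------------------------------------------


def _ray_spectrum(spectrum: SpectralModel) -> np.ndarray:
    """Window-summed beam intensity per energy, including ray sensitivity."""
    Sbar = spectrum.beam_density  # (ni,)
    if spectrum.ray_sensitivity is None:
        return Sbar[None, :]  # broadcasts over rays
    return np.asarray(spectrum.ray_sensitivity, float)[:, None] * Sbar[None, :]


def ct_loss(
    y: np.ndarray,
    spectrum: SpectralModel,
    att: AttenuationTable,
    counts: np.ndarray,
) -> float:
    """Modified negative log-likelihood ``gc(y) + gd(y)`` of the count data.

    Raises if any window-ray intensity is nonpositive where its count is
    positive (outside the domain of the log term); zero-count terms
    contribute only through gc.
    """
    counts = np.asarray(counts, dtype=float)
    lam = window_intensities(y, spectrum, att, expfun=qexp)  # (nw, nl)
    gc = float(lam.sum())
    pos = counts > 0
    if np.any(lam[pos] <= 0):
        raise ValueError("nonpositive window intensity at a positive count")
    gd = -float(np.sum(counts[pos] * np.log(lam[pos])))
    return gc + gd


def ct_grad_gc(
    y: np.ndarray, spectrum: SpectralModel, att: AttenuationTable
) -> np.ndarray:
    """``d gc / d y_{lm} = -sum_i Sbar_{li} mu_{mi} qexp'(t_{li})``, shape (nl, nm)."""
    t = path_exponents(y, att)
    e1 = qexp_d1(t)
    return -(e1 * _ray_spectrum(spectrum)) @ att.mu.T


def ct_grad_gd(
    y: np.ndarray,
    spectrum: SpectralModel,
    att: AttenuationTable,
    counts: np.ndarray,
) -> np.ndarray:
    """``d gd / d y_{lm} = sum_w C_{wl} Lam_{wl}^{-1} sum_i S_{wli} mu_{mi} qexp'``."""
    counts = np.asarray(counts, dtype=float)
    t = path_exponents(y, att)
    e1 = qexp_d1(t)
    lam = window_intensities(y, spectrum, att, expfun=qexp)
    pos = counts > 0
    if np.any(lam[pos] <= 0):
        raise ValueError("nonpositive window intensity at a positive count")
    ratio = np.zeros_like(lam)
    ratio[pos] = counts[pos] / lam[pos]
    W = ratio.T @ spectrum.S_wi  # (nl, ni)
    if spectrum.ray_sensitivity is not None:
        W = W * np.asarray(spectrum.ray_sensitivity, float)[:, None]
    return (W * e1) @ att.mu.T


def ct_grad_g(
    y: np.ndarray,
    spectrum: SpectralModel,
    att: AttenuationTable,
    counts: np.ndarray,
) -> np.ndarray:
    """Gradient of the full loss ``g = gc + gd``."""
    return ct_grad_gc(y, spectrum, att) + ct_grad_gd(y, spectrum, att, counts)


# ---------------------------------------------------------------------------
# Preconditioners and update steps
# ---------------------------------------------------------------------------


@dataclass
class Preconditioners:
    """Diagonal row/column-sum preconditioners ``Qf`` and ``SigmaTilde``.

    ``(Qf)_kk = sigma * sum_l P_lk`` and ``SigmaTilde_ll = sigma / sum_k P_lk``
    make the induced ``Hf = Qf (x) I - A' Sigma A`` positive semidefinite:
    the row sums of ``P' SigmaTilde P`` equal the Qf diagonal exactly, so
    Hf is diagonally dominant with nonnegative diagonal (the classic
    diagonal-preconditioning lemma for products of nonnegative matrices).
    Pixels untouched by any ray (zero column sum) and rays missing the
    image (zero row sum) have their sums floored so the corresponding
    variables are effectively frozen rather than dividing by zero.
    """

    Qf_diag: np.ndarray
    SigmaTilde_diag: np.ndarray
    sigma: float


def build_preconditioners(P: sp.spmatrix, sigma: float) -> Preconditioners:
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    col = np.asarray(P.sum(axis=0)).ravel()
    row = np.asarray(P.sum(axis=1)).ravel()
    floor = 1e-12 * max(float(P.max()), 1e-300)
    col = np.maximum(col, floor)
    row = np.maximum(row, floor)
    return Preconditioners(
        Qf_diag=sigma * col, SigmaTilde_diag=sigma / row, sigma=float(sigma)
    )


def ct_x_update(
    x: np.ndarray,
    y: np.ndarray,
    u: np.ndarray,
    P: sp.spmatrix,
    pre: Preconditioners,
) -> np.ndarray:
    """Closed-form x step: ``x - Qf^{-1} P'(u + SigmaTilde (P x - y))`` per material.

    With ``f == 0`` and ``Hf = Qf (x) I - A' Sigma A`` the x subproblem is an
    unconstrained quadratic whose unique minimizer this is.
    """
    if np.any(pre.Qf_diag <= 0):
        raise ValueError("Qf diagonal must be strictly positive")
    r = np.asarray(P @ x) - y
    return x - (P.T @ (u + pre.SigmaTilde_diag[:, None] * r)) / pre.Qf_diag[:, None]


@dataclass
class CtReconConfig:
    """Reconstruction settings: ADMM penalty scale and Newton tolerances."""

    sigma: float = 10.0
    T: int = 1000
    newton_tol: float = 1e-10
    newton_max_iter: int = 50
    newton_max_backtracks: int = 30
    init: Optional[tuple] = None

    def __post_init__(self):
        if not self.sigma > 0 or not self.newton_tol > 0:
            raise ValueError("sigma and newton_tol must be positive")


def ct_y_update(
    y_t: np.ndarray,
    px_next: np.ndarray,
    u: np.ndarray,
    spectrum: SpectralModel,
    att: AttenuationTable,
    counts: np.ndarray,
    pre: Preconditioners,
    cfg: CtReconConfig,
) -> tuple:
    """Damped-Newton y step, one small strictly convex problem per ray.

    For each ray l independently minimizes

        gc_l(y_l) + <y_l, d_l> + (SigmaTilde_ll / 2) ||y_l - (P x_next)_l||^2

    with ``d_l = (grad gd(y_t))_l - u_l`` (the concave count term is
    linearized at ``y_t``). ``px_next`` is the forward projection of the
    new image. Newton steps with Armijo backtracking (halving), started at
    the previous ``y_l``; terminates when every ray's subproblem gradient
    norm is at most ``cfg.newton_tol``. Returns ``(y_next, max_residual)``.
    """
    st = pre.SigmaTilde_diag
    if np.any(st <= 0):
        raise ValueError("SigmaTilde diagonal must be strictly positive")
    mu = att.mu  # (nm, ni)
    nm = mu.shape[0]
    Sray = _ray_spectrum(spectrum)  # (1 or nl, ni)
    d = ct_grad_gd(y_t, spectrum, att, counts) - u

    def sub_value(y, idx):
        t = path_exponents(y, att)
        S = Sray if Sray.shape[0] == 1 else Sray[idx]
        gc = (S * qexp(t)).sum(axis=1)
        quad = 0.5 * st[idx] * ((y - px_next[idx]) ** 2).sum(axis=1)
        return gc + (y * d[idx]).sum(axis=1) + quad

    def sub_grad(y, idx):
        t = path_exponents(y, att)
        S = Sray if Sray.shape[0] == 1 else Sray[idx]
        e1 = qexp_d1(t)
        ggc = -(S * e1) @ mu.T
        # rounding floor of the gradient: sum of the magnitudes of the
        # terms that cancel in its assembly, per ray
        gmag = (S * e1) @ np.abs(mu).T + np.abs(d[idx]) + st[idx, None] * np.abs(
            y - px_next[idx]
        )
        scale = np.linalg.norm(gmag, axis=1)
        return ggc + d[idx] + st[idx, None] * (y - px_next[idx]), scale

    def sub_hess(y, idx):
        t = path_exponents(y, att)
        S = Sray if Sray.shape[0] == 1 else Sray[idx]
        H = np.einsum("li,mi,ni->lmn", S * qexp_d2(t), mu, mu)
        H += st[idx, None, None] * np.eye(nm)[None, :, :]
        return H

    eps = np.finfo(float).eps
    y = np.array(y_t, dtype=float, copy=True)
    all_idx = np.arange(y.shape[0])
    # rays frozen at the floating-point floor: their Newton decrement is
    # below the rounding error of the objective, so no representable step
    # can improve them further
    frozen = np.zeros(y.shape[0], dtype=bool)
    for _ in range(cfg.newton_max_iter):
        g, scale = sub_grad(y, all_idx)
        gn = np.linalg.norm(g, axis=1)
        # a gradient cannot be resolved below the rounding error of its
        # own assembly; widen the tolerance per ray to that floor
        tol_eff = np.maximum(cfg.newton_tol, 64.0 * eps * scale)
        active = np.flatnonzero((gn > tol_eff) & ~frozen)
        if active.size == 0:
            break
        ya = y[active]
        H = sub_hess(ya, active)
        step = -np.linalg.solve(H, g[active][:, :, None])[:, :, 0]
        f0 = sub_value(ya, active)
        descent = (g[active] * step).sum(axis=1)  # negative by convexity
        # once the Newton decrement is below the rounding resolution of f,
        # Armijo is blind; the step is then provably tiny (|step|^2 <=
        # decrement / min eigenvalue), so take it at full length
        pure = -descent <= 8.0 * eps * (1.0 + np.abs(f0))
        alpha = np.ones(active.size)
        accepted = pure.copy()
        y_new = ya + alpha[:, None] * step * accepted[:, None]
        for _bt in range(cfg.newton_max_backtracks):
            rem = ~accepted
            if not rem.any():
                break
            trial = ya[rem] + alpha[rem, None] * step[rem]
            f_trial = sub_value(trial, active[rem])
            # relative slack keeps Armijo meaningful when the required
            # decrease nears the rounding level of f itself
            slack = 4.0 * eps * (1.0 + np.abs(f0[rem]))
            ok = f_trial <= f0[rem] + 1e-4 * alpha[rem] * descent[rem] + slack
            rem_idx = np.flatnonzero(rem)
            y_new[rem_idx[ok]] = trial[ok]
            accepted[rem_idx[ok]] = True
            alpha[rem_idx[~ok]] *= 0.5
        frozen[active[~accepted]] = True
        y[active[accepted]] = y_new[accepted]
    g, scale = sub_grad(y, all_idx)
    gn = np.linalg.norm(g, axis=1)
    tol_eff = np.maximum(cfg.newton_tol, 64.0 * eps * scale)
    max_resid = float(gn.max()) if gn.size else 0.0
    bad = (gn > tol_eff) & ~frozen
    if np.any(bad):
        worst = int(np.argmax(np.where(bad, gn, -np.inf)))
        raise NewtonError(
            f"Newton did not reach tol {cfg.newton_tol:g} within "
            f"{cfg.newton_max_iter} iterations (worst ray {worst}, "
            f"residual {gn[worst]:.3e})"
        )
    return y, max_resid


# ---------------------------------------------------------------------------
# Full reconstruction driver
# ---------------------------------------------------------------------------


def run_ct_recon(
    P: sp.spmatrix,
    spectrum: SpectralModel,
    att: AttenuationTable,
    counts: np.ndarray,
    cfg: CtReconConfig,
    truth: Optional[np.ndarray] = None,
    store_history: bool = True,
) -> RunResult:
    """Wire the CT updates into the generic ADMM engine and run ``cfg.T`` sweeps.

    ``truth`` is the ground-truth phantom (nk, nm) when known (simulation);
    RMSE is logged as ``||x_t - x_true||_2 / sqrt(nk)``. Extra log columns:
    ``loss_Pxt`` (data loss at the current image's projection) and
    ``max_newton_residual``. The staggered iterate pairs needed by the
    restricted-strong-convexity diagnostic are stored when
    ``store_history`` is set.
    """
    nl, nk = P.shape
    nm = att.nm
    counts = np.asarray(counts)
    if counts.shape != (spectrum.nw, nl):
        raise ValueError("counts shape does not match spectrum/geometry")
    pre = build_preconditioners(P, cfg.sigma)

    def a_fwd(xv):
        return np.asarray(P @ xv.reshape(nk, nm)).ravel()

    def a_adj(rv):
        return np.asarray(P.T @ rv.reshape(nl, nm)).ravel()

    A = LinearMap(forward=a_fwd, adjoint=a_adj, n_in=nk * nm, n_out=nl * nm)
    B = LinearMap.scaled_identity(nl * nm, -1.0)

    cell = {"max_newton_residual": np.nan, "warned_pos_exponent": False}

    def y_solver(y_vec, Ax_vec, u_vec):
        y_mat = y_vec.reshape(nl, nm)
        if not cell["warned_pos_exponent"] and np.any(path_exponents(y_mat, att) > 0):
            cell["warned_pos_exponent"] = True
            warnings.warn(
                "iterate has negative path lengths (positive exponent arguments); "
                "the Hg = 0 step-size condition is only guaranteed on the "
                "nonpositive-exponent region",
                PositiveExponentWarning,
                stacklevel=2,
            )
        y_next, resid = ct_y_update(
            y_mat,
            Ax_vec.reshape(nl, nm),
            u_vec.reshape(nl, nm),
            spectrum,
            att,
            counts,
            pre,
            cfg,
        )
        cell["max_newton_residual"] = resid
        return y_next.ravel()

    problem = SplitProblem(
        dim_x=nk * nm,
        dim_y=nl * nm,
        dim_c=nl * nm,
        A=A,
        B=B,
        gc_value=lambda yv: float(
            window_intensities(yv.reshape(nl, nm), spectrum, att, expfun=qexp).sum()
        ),
        gd_value=lambda yv: ct_loss(yv.reshape(nl, nm), spectrum, att, counts)
        - float(window_intensities(yv.reshape(nl, nm), spectrum, att, expfun=qexp).sum()),
        gd_grad=lambda yv: ct_grad_gd(yv.reshape(nl, nm), spectrum, att, counts).ravel(),
        y_subproblem_solver=y_solver,
    )
    step_cfg = StepConfig(
        sigma=np.repeat(pre.SigmaTilde_diag, nm),
        Df_diag=np.repeat(pre.Qf_diag, nm),
        Eg_diag=np.repeat(pre.SigmaTilde_diag, nm),
    )

    def extra_log(t, state):
        y_proj = np.asarray(P @ state.x.reshape(nk, nm))
        return {
            "loss_Pxt": ct_loss(y_proj, spectrum, att, counts),
            "max_newton_residual": cell["max_newton_residual"],
        }

    truth_pair = None
    if truth is not None:
        truth = np.asarray(truth, dtype=float)
        truth_pair = (truth.ravel(), np.asarray(P @ truth).ravel())
    return run_admm(
        problem,
        step_cfg,
        T=cfg.T,
        init=cfg.init,
        truth=truth_pair,
        rmse_scale=1.0 / np.sqrt(nk),
        store_history=store_history,
        extra_log=extra_log,
    )


# ---------------------------------------------------------------------------
# Restricted-strong-convexity and first-order-optimality diagnostics
# ---------------------------------------------------------------------------


def rsc_alpha_series(
    history: list,
    truth_y: np.ndarray,
    grad_g: Callable[[np.ndarray], np.ndarray],
    sigma_diag: np.ndarray,
    apply_A: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """Empirical restricted-strong-convexity ratio per iteration.

    For each staggered pair ``(x_{t+1}, y_t)`` in ``history``:

        alpha_t = [ <y_t - y~, grad g(y_t) - grad g(y~)>
                    + 1/2 ||A x_{t+1} - y_t||_Sigma^2 ] / ||y_t - y~||_2^2

    where ``y~`` is the projection of the true image. Restricted strong
    convexity along the algorithm's path means alpha_t stays bounded away
    from zero. Entries with ``||y_t - y~|| <= 1e-12`` are undefined and
    returned as NaN.
    """
    ty = np.asarray(truth_y, dtype=float).ravel()
    g_true = grad_g(ty)
    out = np.full(len(history), np.nan)
    for t, (x_next, y_prev) in enumerate(history):
        dy = y_prev.ravel() - ty
        denom = float(np.dot(dy, dy))
        if denom <= 1e-12:
            continue
        inner = float(np.dot(dy, grad_g(y_prev.ravel()) - g_true))
        r = apply_A(x_next.ravel()) - y_prev.ravel()
        penalty = 0.5 * float(np.dot(r, sigma_diag * r))
        out[t] = (inner + penalty) / denom
    return out


def fosp_gradient_ratio(
    truth_y: np.ndarray,
    spectrum: SpectralModel,
    att: AttenuationTable,
    counts: np.ndarray,
) -> float:
    """``||grad g(y~)||_2 / ||grad g(0)||_2`` — approximate stationarity at truth.

    Small values certify that the true projection is an approximate
    first-order stationary point of the (noisy) likelihood; with counts
    set to their exact expectations the ratio is zero to machine precision.
    """
    g_true = ct_grad_g(truth_y, spectrum, att, counts)
    g_zero = ct_grad_g(np.zeros_like(truth_y), spectrum, att, counts)
    denom = float(np.linalg.norm(g_zero))
    if denom == 0.0:
        raise ZeroDivisionError("gradient at the zero image vanishes")
    return float(np.linalg.norm(g_true)) / denom
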