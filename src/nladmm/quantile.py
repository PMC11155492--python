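"""Sparse high-dimensional quantile regression via linearized ADMM.

Solves the penalized check-loss problem

    min_x  (1/n) sum_i l_q(w_i - phi_i' x) + lam * sum_j beta*log(1 + |x_j|/beta)
           subject to ||x||_2 <= R   (R = +inf by default)

by splitting ``y = Phi x`` so that ``A = Phi``, ``B = -I``, ``c = 0``.
The objective splits as ``fc(x) = lam*||x||_1 + ball indicator`` (the l1
majorant of the log penalty plus the constraint), ``fd(x) = lam *
sum_j (beta*log(1+|x_j|/beta) - |x_j|)`` (smooth, concave, with Hessian
bounded below by -lam/beta), ``gc(y) = (1/n) sum_i l_q(w_i - y_i)`` and
``gd == 0``.

Step sizes: with Sigma = sigma*I_n we take Hf = sigma*(gamma*I - Phi'Phi)
where gamma is (at least) the squared spectral norm of Phi, so that
Df = Hf + Phi' Sigma Phi = sigma*gamma*I is diagonal and Hf is PSD; both
update steps are then closed-form proxes (soft-threshold + ball projection
for x, the per-coordinate quantile prox for y). Hg = 0, so
Eg = B' Sigma B = sigma*I. The concavity bound on fd makes
Hf >= hess fd automatic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ConfigurationError, LinearMap, RunResult, SplitProblem, StepConfig, run_admm
from .prox import (
    log_penalty_smooth_grad,
    log_penalty_smooth_value,
    log_penalty_value,
    prox_l1_ball,
    prox_quantile,
    quantile_loss,
)

__all__ = [
    "QuantileProblemSpec",
    "power_iteration_sq_norm",
    "qr_objective",
    "assemble_qr_problem",
    "fit_quantile",
]


@dataclass
class QuantileProblemSpec:
    """Data and tuning parameters of one quantile-regression fit.

    ``gamma`` must dominate the squared spectral norm of ``Phi`` (it
    defaults to a power-iteration estimate, inflated by a factor
    ``1 + 1e-7`` — an order above the power-iteration tolerance — so Hf
    stays PSD under floating point). ``radius`` is the
    l2-ball constraint R, +inf by default since the iterates do not
    diverge in practice.
    """

    Phi: np.ndarray
    w: np.ndarray
    q: float = 0.5
    lam: float = 0.1
    beta: float = 0.5
    radius: float = np.inf
    sigma: float = 2e-3
    gamma: Optional[float] = None
    T: int = 1000

    def __post_init__(self):
        self.Phi = np.asarray(self.Phi, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.Phi.ndim != 2 or self.w.shape != (self.Phi.shape[0],):
            raise ConfigurationError("Phi must be (n, d) with w of length n")
        if not 0 < self.q < 1:
            raise ConfigurationError("q must lie in (0, 1)")
        if self.lam < 0 or not self.beta > 0 or not self.radius > 0:
            raise ConfigurationError("need lam >= 0, beta > 0, radius > 0")
        if not self.sigma > 0:
            raise ConfigurationError("sigma must be positive")

    @property
    def n(self) -> int:
        return self.Phi.shape[0]

    @property
    def d(self) -> int:
        return self.Phi.shape[1]


def power_iteration_sq_norm(
    Phi: np.ndarray, tol: float = 1e-8, max_iter: int = 500, seed: int = 0
) -> float:
    """Squared spectral norm of Phi (largest eigenvalue of Phi'Phi)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(Phi.shape[1])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        z = Phi.T @ (Phi @ v)
        lam_new = float(np.linalg.norm(z))
        if lam_new == 0.0:
            return 0.0
        v = z / lam_new
        if abs(lam_new - lam) <= tol * max(lam_new, 1.0):
            lam = lam_new
            break
        lam = lam_new
    return lam


def qr_objective(x: np.ndarray, spec: QuantileProblemSpec) -> float:
    """Penalized quantile loss ``(1/n) sum_i l_q(w_i - phi_i'x) + log penalty``."""
    resid = spec.w - spec.Phi @ x
    return float(np.mean(quantile_loss(resid, spec.q))) + log_penalty_value(
        x, spec.lam, spec.beta
    )


def assemble_qr_problem(spec: QuantileProblemSpec):
    """Build the (SplitProblem, StepConfig) pair with closed-form updates.

    Raises a configuration error when a user-supplied ``gamma`` is below
    the squared spectral norm of Phi, which would make Hf indefinite.
    """
    n, d = spec.n, spec.d
    sq_norm = power_iteration_sq_norm(spec.Phi)
    if spec.gamma is None:
        gamma = sq_norm * (1.0 + 1e-7)
    else:
        gamma = float(spec.gamma)
        if gamma < sq_norm * (1.0 - 1e-8):
            raise ConfigurationError(
                f"gamma={gamma:g} is below ||Phi||^2~{sq_norm:g}; Hf would be indefinite"
            )
    A = LinearMap.from_matrix(spec.Phi)
    B = LinearMap.scaled_identity(n, -1.0)

    def fc_prox(v, metric):
        return prox_l1_ball(v, spec.lam / metric, spec.radius)

    def fc_value(x):
        if np.linalg.norm(x) > spec.radius * (1.0 + 1e-12):
            return np.inf
        return spec.lam * float(np.sum(np.abs(x)))

    def gc_prox(v, metric):
        return prox_quantile(v, spec.w, spec.q, a=1.0 / n, rho=metric)

    problem = SplitProblem(
        dim_x=d,
        dim_y=n,
        dim_c=n,
        A=A,
        B=B,
        fc_prox=fc_prox,
        fc_value=fc_value,
        fd_value=lambda x: log_penalty_smooth_value(x, spec.lam, spec.beta),
        fd_grad=lambda x: log_penalty_smooth_grad(x, spec.lam, spec.beta),
        gc_prox=gc_prox,
        gc_value=lambda y: float(np.mean(quantile_loss(spec.w - y, spec.q))),
    )
    cfg = StepConfig(
        sigma=np.full(n, spec.sigma),
        Df_diag=np.full(d, spec.sigma * gamma),
        Eg_diag=np.full(n, spec.sigma),
    )
    return problem, cfg


def fit_quantile(
    spec: QuantileProblemSpec,
    init: Optional[tuple] = None,
    truth: Optional[np.ndarray] = None,
    store_history: bool = False,
) -> RunResult:
    """Run ``spec.T`` ADMM sweeps on the assembled problem.

    Logs the penalized loss at both the current iterate and the running
    average (columns ``loss_x``, ``loss_xbar``), plus the RMSE
    ``||x - x_true||_2 / sqrt(d)`` for both when ``truth`` is given.
    """
    problem, cfg = assemble_qr_problem(spec)

    def extra_log(t, state):
        return {
            "loss_x": qr_objective(state.x, spec),
            "loss_xbar": qr_objective(state.x_bar, spec),
        }

    truth_pair = None
    if truth is not None:
        truth = np.asarray(truth, dtype=float)
        truth_pair = (truth, spec.Phi @ truth)
    return run_admm(
        problem,
        cfg,
        T=spec.T,
        init=init,
        truth=truth_pair,
        rmse_scale=1.0 / np.sqrt(spec.d),
        store_history=store_history,
        extra_log=extra_log,
    )
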