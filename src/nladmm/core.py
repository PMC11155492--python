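"""Linearized ADMM engine for nonconvex composite problems.

Solves ``min f(x) + g(y)  s.t.  A x + B y = c`` where ``f = fc + fd`` and
``g = gc + gd`` with ``fc, gc`` convex (possibly nonsmooth, possibly with
restricted domains) and ``fd, gd`` twice differentiable (possibly
nonconvex). Each sweep performs

    x_{t+1} = argmin_x fc(x) + <x, grad fd(x_t) + A'u_t>
              + 1/2 ||A x + B y_t - c||_Sigma^2 + 1/2 ||x - x_t||_Hf^2
    y_{t+1} = argmin_y gc(y) + <y, grad gd(y_t) + B'u_t>
              + 1/2 ||A x_{t+1} + B y - c||_Sigma^2 + 1/2 ||y - y_t||_Hg^2
    u_{t+1} = u_t + Sigma (A x_{t+1} + B y_{t+1} - c)

The engine's fast path takes the *summed* step metrics
``Df = Hf + A' Sigma A`` and ``Eg = Hg + B' Sigma B`` as positive diagonal
vectors: in that case each subproblem is exactly a prox in a diagonal
metric, which is how both bundled applications are set up. Convergence in
the nonconvex setting is for the running averages ``xbar_T = mean(x_1..x_T)``
(and likewise ``ybar_T``), so those are accumulated and returned alongside
the final iterates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "OracleError",
    "LinearMap",
    "SplitProblem",
    "StepConfig",
    "AdmmState",
    "RunResult",
    "x_update",
    "y_update",
    "u_update",
    "run_admm",
    "augmented_lagrangian",
    "primal_residual",
    "verify_step_conditions",
    "StepConditionReport",
]


class ConfigurationError(ValueError):
    """Invalid solver configuration (e.g. nonpositive step metric)."""


class OracleError(RuntimeError):
    """A user-supplied oracle returned invalid (non-finite) values."""


# ---------------------------------------------------------------------------
# Problem data
# ---------------------------------------------------------------------------


@dataclass
class LinearMap:
    """Matrix-free linear operator with explicit forward/adjoint oracles."""

    forward: Callable[[np.ndarray], np.ndarray]
    adjoint: Callable[[np.ndarray], np.ndarray]
    n_in: int
    n_out: int

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return self.forward(v)

    def T(self, v: np.ndarray) -> np.ndarray:
        return self.adjoint(v)

    @staticmethod
    def from_matrix(M) -> "LinearMap":
        """Wrap a dense or scipy-sparse matrix."""
        n_out, n_in = M.shape
        MT = M.T
        return LinearMap(
            forward=lambda v: np.asarray(M @ v),
            adjoint=lambda v: np.asarray(MT @ v),
            n_in=n_in,
            n_out=n_out,
        )

    @staticmethod
    def scaled_identity(n: int, scale: float = 1.0) -> "LinearMap":
        return LinearMap(
            forward=lambda v: scale * v,
            adjoint=lambda v: scale * v,
            n_in=n,
            n_out=n,
        )

    def to_dense(self) -> np.ndarray:
        """Materialize the operator by probing with basis vectors (small n only)."""
        out = np.zeros((self.n_out, self.n_in))
        e = np.zeros(self.n_in)
        for j in range(self.n_in):
            e[j] = 1.0
            out[:, j] = self.forward(e)
            e[j] = 0.0
        return out

    def check_adjoint(self, rng=None, n_probe: int = 5, tol: float = 1e-8) -> bool:
        """Verify <A v, u> == <v, A' u> on random probe pairs."""
        rng = np.random.default_rng(rng)
        for _ in range(n_probe):
            v = rng.standard_normal(self.n_in)
            u = rng.standard_normal(self.n_out)
            lhs = float(np.dot(self.forward(v), u))
            rhs = float(np.dot(v, self.adjoint(u)))
            if abs(lhs - rhs) > tol * (1.0 + abs(lhs)):
                return False
        return True


def _zero_value(v: np.ndarray) -> float:
    return 0.0


def _zero_grad(v: np.ndarray) -> np.ndarray:
    return np.zeros_like(v)


def _identity_prox(v: np.ndarray, metric: np.ndarray) -> np.ndarray:
    return v


@dataclass
class SplitProblem:
    """Oracle bundle defining ``min fc(x)+fd(x)+gc(y)+gd(y) : Ax+By=c``.

    ``fc_prox(v, metric)`` must return
    ``argmin_x fc(x) + 1/2 sum_j metric_j (x_j - v_j)^2`` and always return
    an in-domain point; value oracles return ``+inf`` outside the domain
    instead of raising. ``y_subproblem_solver``, if given, replaces the
    prox-based y update: it is called as ``solver(y_t, Ax_next, u_t)`` and
    must return a point whose subproblem gradient norm is within the
    solver's own tolerance (used by the CT application, whose gc is smooth
    but not prox-friendly).
    """

    dim_x: int
    dim_y: int
    dim_c: int
    A: LinearMap
    B: LinearMap
    c: np.ndarray = None
    fc_prox: Callable = _identity_prox
    fc_value: Callable = _zero_value
    fd_value: Callable = _zero_value
    fd_grad: Callable = _zero_grad
    gc_prox: Callable = _identity_prox
    gc_value: Callable = _zero_value
    gd_value: Callable = _zero_value
    gd_grad: Callable = _zero_grad
    y_subproblem_solver: Optional[Callable] = None

    def __post_init__(self):
        if self.c is None:
            self.c = np.zeros(self.dim_c)
        self.c = np.asarray(self.c, dtype=float)
        if self.A.n_in != self.dim_x or self.A.n_out != self.dim_c:
            raise ConfigurationError("A has inconsistent dimensions")
        if self.B.n_in != self.dim_y or self.B.n_out != self.dim_c:
            raise ConfigurationError("B has inconsistent dimensions")
        if self.c.shape != (self.dim_c,):
            raise ConfigurationError("c has inconsistent dimension")

    def f_value(self, x: np.ndarray) -> float:
        return float(self.fc_value(x)) + float(self.fd_value(x))

    def g_value(self, y: np.ndarray) -> float:
        return float(self.gc_value(y)) + float(self.gd_value(y))

    def constraint_residual(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.A(x) + self.B(y) - self.c


@dataclass
class StepConfig:
    """Penalty matrix Sigma and the summed step metrics of the fast path.

    ``sigma`` is either a positive vector (diagonal Sigma, the fast path)
    or a dense SPD matrix (small instances only). ``Df_diag`` and
    ``Eg_diag`` are the diagonals of ``Hf + A' Sigma A`` and
    ``Hg + B' Sigma B``; the updates only ever use these sums, and both
    applications choose Hf/Hg precisely so the sums are diagonal. Strict
    positivity of the diagonals is the positive-definiteness requirement
    on the summed metrics.
    """

    sigma: np.ndarray
    Df_diag: np.ndarray
    Eg_diag: np.ndarray

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.Df_diag = np.asarray(self.Df_diag, dtype=float)
        self.Eg_diag = np.asarray(self.Eg_diag, dtype=float)
        if self.sigma.ndim == 1:
            if np.any(self.sigma <= 0):
                raise ConfigurationError("diagonal Sigma must be strictly positive")
        elif self.sigma.ndim == 2:
            if not np.allclose(self.sigma, self.sigma.T):
                raise ConfigurationError("dense Sigma must be symmetric")
            if np.any(np.linalg.eigvalsh(self.sigma) <= 0):
                raise ConfigurationError("dense Sigma must be positive definite")
        else:
            raise ConfigurationError("sigma must be a vector or a matrix")
        for name, d in (("Df_diag", self.Df_diag), ("Eg_diag", self.Eg_diag)):
            if d.ndim != 1 or np.any(d <= 0) or not np.all(np.isfinite(d)):
                raise ConfigurationError(f"{name} must be a strictly positive vector")

    @property
    def sigma_is_diagonal(self) -> bool:
        return self.sigma.ndim == 1

    def sigma_apply(self, r: np.ndarray) -> np.ndarray:
        if self.sigma_is_diagonal:
            return self.sigma * r
        return self.sigma @ r

    def sigma_quadform(self, r: np.ndarray) -> float:
        return float(np.dot(r, self.sigma_apply(r)))

    def sigma_dense(self, dim_c: int) -> np.ndarray:
        if self.sigma_is_diagonal:
            return np.diag(self.sigma)
        return self.sigma


@dataclass
class AdmmState:
    """Current iterates and exact running sums for the iterate averages."""

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    t: int = 0
    x_sum: np.ndarray = None
    y_sum: np.ndarray = None
    n_avg: int = 0

    def __post_init__(self):
        if self.x_sum is None:
            self.x_sum = np.zeros_like(self.x)
        if self.y_sum is None:
            self.y_sum = np.zeros_like(self.y)

    @property
    def x_bar(self) -> np.ndarray:
        return self.x_sum / max(self.n_avg, 1)

    @property
    def y_bar(self) -> np.ndarray:
        return self.y_sum / max(self.n_avg, 1)


@dataclass
class RunResult:
    """Final state, averaged iterates, and the per-iteration log table."""

    state: AdmmState
    x_bar: np.ndarray
    y_bar: np.ndarray
    log: pd.DataFrame
    history: Optional[list] = None  # list of (x_{t+1}, y_t) staggered pairs

    @property
    def x(self) -> np.ndarray:
        return self.state.x

    @property
    def y(self) -> np.ndarray:
        return self.state.y


# ---------------------------------------------------------------------------
# Update steps
# ---------------------------------------------------------------------------


def _require_finite(v: np.ndarray, what: str, t: Optional[int] = None) -> np.ndarray:
    if not np.all(np.isfinite(v)):
        where = f" at iteration {t}" if t is not None else ""
        raise OracleError(f"{what} returned non-finite values{where}")
    return v


def x_update(state: AdmmState, problem: SplitProblem, cfg: StepConfig) -> np.ndarray:
    """One linearized x step: prox of fc in the diagonal metric Df.

    The subproblem equals (up to an additive constant)
    ``fc(x) + 1/2 ||x - v||_Df^2`` with
    ``v = x_t - Df^{-1} [grad fd(x_t) + A'(u_t + Sigma(A x_t + B y_t - c))]``,
    so the returned point is its exact minimizer and weakly decreases the
    subproblem objective relative to ``x_t``.
    """
    r = problem.constraint_residual(state.x, state.y)
    grad = problem.fd_grad(state.x) + problem.A.adjoint(state.u + cfg.sigma_apply(r))
    v = state.x - grad / cfg.Df_diag
    x_next = np.asarray(problem.fc_prox(v, cfg.Df_diag), dtype=float)
    return _require_finite(x_next, "fc_prox", state.t)


def y_update(
    state: AdmmState, x_next: np.ndarray, problem: SplitProblem, cfg: StepConfig
) -> np.ndarray:
    """One linearized y step, using ``x_next`` in the penalty term.

    Dispatches to ``y_subproblem_solver`` when registered; otherwise a prox
    of gc in the diagonal metric Eg at
    ``v = y_t - Eg^{-1} [grad gd(y_t) + B'(u_t + Sigma(A x_next + B y_t - c))]``.
    """
    Ax = problem.A(x_next)
    if problem.y_subproblem_solver is not None:
        y_next = np.asarray(problem.y_subproblem_solver(state.y, Ax, state.u), dtype=float)
        return _require_finite(y_next, "y_subproblem_solver", state.t)
    r = Ax + problem.B(state.y) - problem.c
    grad = problem.gd_grad(state.y) + problem.B.adjoint(state.u + cfg.sigma_apply(r))
    v = state.y - grad / cfg.Eg_diag
    y_next = np.asarray(problem.gc_prox(v, cfg.Eg_diag), dtype=float)
    return _require_finite(y_next, "gc_prox", state.t)


def u_update(
    state: AdmmState,
    x_next: np.ndarray,
    y_next: np.ndarray,
    problem: SplitProblem,
    cfg: StepConfig,
) -> np.ndarray:
    """Dual ascent: ``u_{t+1} = u_t + Sigma (A x_{t+1} + B y_{t+1} - c)``."""
    r = problem.A(x_next) + problem.B(y_next) - problem.c
    return state.u + cfg.sigma_apply(r)


# ---------------------------------------------------------------------------
# Objective bookkeeping
# ---------------------------------------------------------------------------


def augmented_lagrangian(
    x: np.ndarray, y: np.ndarray, u: np.ndarray, problem: SplitProblem, cfg: StepConfig
) -> float:
    """``f(x) + g(y) + <u, Ax+By-c> + 1/2 ||Ax+By-c||_Sigma^2`` (extended real)."""
    fx = problem.f_value(x)
    gy = problem.g_value(y)
    if not np.isfinite(fx) or not np.isfinite(gy):
        return np.inf
    r = problem.constraint_residual(x, y)
    return fx + gy + float(np.dot(u, r)) + 0.5 * cfg.sigma_quadform(r)


def primal_residual(
    x: np.ndarray, y: np.ndarray, problem: SplitProblem, cfg: StepConfig
) -> float:
    """Sigma-weighted constraint violation ``||Ax+By-c||_Sigma``; 0 iff feasible."""
    r = problem.constraint_residual(x, y)
    return float(np.sqrt(max(cfg.sigma_quadform(r), 0.0)))


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_admm(
    problem: SplitProblem,
    cfg: StepConfig,
    T: int,
    init: Optional[tuple] = None,
    truth: Optional[tuple] = None,
    rmse_scale: Optional[float] = None,
    burn_in: int = 0,
    store_history: bool = False,
    extra_log: Optional[Callable] = None,
    early_stop_tol: Optional[float] = None,
) -> RunResult:
    """Run exactly ``T`` full sweeps of linearized ADMM.

    Parameters
    ----------
    init : optional (x0, y0, u0); defaults to zeros, which is in-domain for
        both bundled applications.
    truth : optional (x_true, y_true) used only for the RMSE log columns;
        ``y_true`` may be None. RMSE is ``rmse_scale * ||x - x_true||_2``
        with ``rmse_scale`` defaulting to ``1/sqrt(dim_x)``.
    burn_in : number of leading iterates excluded from the running
        averages (default 0: all iterates included, matching the averaged
        convergence guarantee).
    store_history : record the staggered pairs ``(x_{t+1}, y_t)`` per
        iteration, as needed by the restricted-strong-convexity diagnostic.
    extra_log : optional callable ``(t, state) -> dict`` appended to each
        log row after the sweep.
    early_stop_tol : optional; when set, stop early once both the primal
        residual and the successive-iterate change fall below it (off by
        default: the averaged-iterate guarantee is stated for a fixed T).
    """
    if T < 1:
        raise ConfigurationError("T must be >= 1")
    if init is None:
        x0 = np.zeros(problem.dim_x)
        y0 = np.zeros(problem.dim_y)
        u0 = np.zeros(problem.dim_c)
    else:
        x0, y0, u0 = (np.asarray(v, dtype=float).copy() for v in init)
    state = AdmmState(x=x0, y=y0, u=u0)
    x_true = y_true = None
    if truth is not None:
        x_true = None if truth[0] is None else np.asarray(truth[0], dtype=float)
        y_true = None if truth[1] is None else np.asarray(truth[1], dtype=float)
    if rmse_scale is None:
        rmse_scale = 1.0 / np.sqrt(problem.dim_x)

    rows = []
    history = [] if store_history else None
    for t in range(T):
        try:
            x_next = x_update(state, problem, cfg)
            if store_history:
                history.append((x_next.copy(), state.y.copy()))
            y_next = y_update(state, x_next, problem, cfg)
            u_next = u_update(state, x_next, y_next, problem, cfg)
        except OracleError:
            raise
        except Exception as exc:  # attach the iteration index to oracle failures
            raise OracleError(f"update failed at iteration {t + 1}: {exc}") from exc
        dx = float(np.linalg.norm(x_next - state.x))
        dy = float(np.linalg.norm(y_next - state.y))
        state.x, state.y, state.u = x_next, y_next, u_next
        state.t = t + 1
        if state.t > burn_in:
            state.x_sum += x_next
            state.y_sum += y_next
            state.n_avg += 1
        row = {
            "t": state.t,
            "objective": problem.f_value(state.x) + problem.g_value(state.y),
            "aug_lagrangian": augmented_lagrangian(state.x, state.y, state.u, problem, cfg),
            "primal_residual": primal_residual(state.x, state.y, problem, cfg),
            "rmse_x": np.nan,
            "rmse_xbar": np.nan,
        }
        if x_true is not None:
            row["rmse_x"] = rmse_scale * float(np.linalg.norm(state.x - x_true))
            row["rmse_xbar"] = rmse_scale * float(np.linalg.norm(state.x_bar - x_true))
        if extra_log is not None:
            row.update(extra_log(state.t, state))
        rows.append(row)
        if early_stop_tol is not None:
            if row["primal_residual"] < early_stop_tol and max(dx, dy) < early_stop_tol:
                break
    log = pd.DataFrame(rows)
    return RunResult(
        state=state, x_bar=state.x_bar, y_bar=state.y_bar, log=log, history=history
    )


# ---------------------------------------------------------------------------
# Step-size condition diagnostics (dense mode, small instances)
# ---------------------------------------------------------------------------


@dataclass
class StepConditionReport:
    """Minimum eigenvalues of the step-size condition matrices.

    The conditions are ``Hf >= 0``, ``Hf + A'Sigma A > 0`` and
    ``Hf >= hess fd(x)`` at every probe point (and the g analogues).
    Entries below ``-tol`` are flagged as violations.
    """

    min_eig_Hf: float
    min_eig_Df: float
    min_eig_Hf_minus_hess: list
    min_eig_Hg: float
    min_eig_Eg: float
    min_eig_Hg_minus_hess: list
    violations: list
    tol: float = 1e-8

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_step_conditions(
    problem: SplitProblem,
    cfg: StepConfig,
    Hf: Optional[np.ndarray] = None,
    Hg: Optional[np.ndarray] = None,
    fd_hessian: Optional[Callable] = None,
    gd_hessian: Optional[Callable] = None,
    probes_x: Sequence[np.ndarray] = (),
    probes_y: Sequence[np.ndarray] = (),
    tol: float = 1e-8,
) -> StepConditionReport:
    """Check the step-size matrix conditions by dense eigendecomposition.

    When ``Hf``/``Hg`` are not given they are recovered from the fast path
    as ``diag(Df) - A'Sigma A`` (resp. ``diag(Eg) - B'Sigma B``), which
    requires materializing A and B — small instances only.
    """
    A = problem.A.to_dense()
    B = problem.B.to_dense()
    S = cfg.sigma_dense(problem.dim_c)
    AtSA = A.T @ S @ A
    BtSB = B.T @ S @ B
    if Hf is None:
        Hf = np.diag(cfg.Df_diag) - AtSA
    if Hg is None:
        Hg = np.diag(cfg.Eg_diag) - BtSB
    if Hf.shape != (problem.dim_x, problem.dim_x):
        raise ConfigurationError("Hf dimension mismatch")
    if Hg.shape != (problem.dim_y, problem.dim_y):
        raise ConfigurationError("Hg dimension mismatch")

    def _min_eig(M):
        return float(np.min(np.linalg.eigvalsh(0.5 * (M + M.T))))

    report = StepConditionReport(
        min_eig_Hf=_min_eig(Hf),
        min_eig_Df=_min_eig(Hf + AtSA),
        min_eig_Hf_minus_hess=[],
        min_eig_Hg=_min_eig(Hg),
        min_eig_Eg=_min_eig(Hg + BtSB),
        min_eig_Hg_minus_hess=[],
        violations=[],
        tol=tol,
    )
    checks = [
        ("Hf >= 0", report.min_eig_Hf, False),
        ("Hf + A'Sigma A > 0", report.min_eig_Df, True),
        ("Hg >= 0", report.min_eig_Hg, False),
        ("Hg + B'Sigma B > 0", report.min_eig_Eg, True),
    ]
    for name, val, strict in checks:
        if val < -tol or (strict and val <= 0):
            report.violations.append(name)
    if fd_hessian is not None:
        for i, p in enumerate(probes_x):
            e = _min_eig(Hf - np.asarray(fd_hessian(p)))
            report.min_eig_Hf_minus_hess.append(e)
            if e < -tol:
                report.violations.append(f"Hf >= hess fd at probe {i}")
    if gd_hessian is not None:
        for i, p in enumerate(probes_y):
            e = _min_eig(Hg - np.asarray(gd_hessian(p)))
            report.min_eig_Hg_minus_hess.append(e)
            if e < -tol:
                report.violations.append(f"Hg >= hess gd at probe {i}")
    return report
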