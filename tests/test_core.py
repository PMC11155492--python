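"""Generic ADMM engine: update formulas, invariants, and oracle equivalence."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from nladmm.core import (
    AdmmState,
    ConfigurationError,
    LinearMap,
    SplitProblem,
    StepConfig,
    augmented_lagrangian,
    primal_residual,
    run_admm,
    u_update,
    verify_step_conditions,
    x_update,
    y_update,
)
from nladmm.prox import prox_quantile, quantile_loss, soft_threshold


def identity_problem(n=2, c=None):
    return SplitProblem(
        dim_x=n,
        dim_y=n,
        dim_c=n,
        A=LinearMap.scaled_identity(n, 1.0),
        B=LinearMap.scaled_identity(n, -1.0),
        c=c,
    )


def unit_cfg(n=2):
    return StepConfig(sigma=np.ones(n), Df_diag=np.ones(n), Eg_diag=np.ones(n))


def make_qp(rng, nx, ny, nc, strong=0.5):
    """Random equality-constrained strongly convex QP with its exact KKT point."""
    M = rng.standard_normal((nx, nx))
    Qf = M.T @ M / nx + strong * np.eye(nx)
    M = rng.standard_normal((ny, ny))
    Qg = M.T @ M / ny + strong * np.eye(ny)
    bf = rng.standard_normal(nx)
    bg = rng.standard_normal(ny)
    A = rng.standard_normal((nc, nx))
    B = rng.standard_normal((nc, ny))
    c = rng.standard_normal(nc)
    K = np.block(
        [
            [Qf, np.zeros((nx, ny)), A.T],
            [np.zeros((ny, nx)), Qg, B.T],
            [A, B, np.zeros((nc, nc))],
        ]
    )
    sol = np.linalg.solve(K, np.concatenate([-bf, -bg, c]))
    problem = SplitProblem(
        dim_x=nx,
        dim_y=ny,
        dim_c=nc,
        A=LinearMap.from_matrix(A),
        B=LinearMap.from_matrix(B),
        c=c,
        fc_prox=lambda v, m: np.linalg.solve(Qf + np.diag(m), m * v - bf),
        fc_value=lambda x: 0.5 * x @ Qf @ x + bf @ x,
        gc_prox=lambda v, m: np.linalg.solve(Qg + np.diag(m), m * v - bg),
        gc_value=lambda y: 0.5 * y @ Qg @ y + bg @ y,
    )
    Df = 1.01 * np.linalg.eigvalsh(A.T @ A).max() * np.ones(nx)
    Eg = 1.01 * np.linalg.eigvalsh(B.T @ B).max() * np.ones(ny)
    cfg = StepConfig(sigma=np.ones(nc), Df_diag=Df, Eg_diag=Eg)
    return problem, cfg, sol[:nx], sol[nx : nx + ny], sol[nx + ny :]


class TestLinearMap:
    def test_adjoint_identity_on_probes(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((4, 6))
        assert LinearMap.from_matrix(M).check_adjoint(rng)
        bad = LinearMap(lambda v: M @ v, lambda u: (M + 1.0).T @ u, 6, 4)
        assert not bad.check_adjoint(rng)

    def test_to_dense_roundtrip(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((3, 5))
        np.testing.assert_allclose(LinearMap.from_matrix(M).to_dense(), M)


class TestXUpdate:
    def test_stationary_feasible_point(self):
        problem = identity_problem()
        state = AdmmState(x=np.ones(2), y=np.ones(2), u=np.zeros(2))
        np.testing.assert_allclose(x_update(state, problem, unit_cfg()), [1.0, 1.0])

    def test_soft_threshold_path(self):
        # fc = ||.||_1 with Df = 1: the step is exactly a soft threshold at 1
        problem = identity_problem()
        problem.fc_prox = lambda v, m: soft_threshold(v, 1.0 / m)
        problem.fc_value = lambda x: float(np.abs(x).sum())
        # choose state so the prox input v is exactly (2, -0.5)
        state = AdmmState(x=np.array([2.0, -0.5]), y=np.array([2.0, -0.5]), u=np.zeros(2))
        np.testing.assert_allclose(x_update(state, problem, unit_cfg()), [1.0, 0.0])

    def test_quadratic_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        nx = ny = nc = 5
        problem, cfg, *_ = make_qp(rng, nx, ny, nc)
        state = AdmmState(
            x=rng.standard_normal(nx), y=rng.standard_normal(ny), u=rng.standard_normal(nc)
        )
        got = x_update(state, problem, cfg)
        # oracle: dense solve of the full subproblem KKT system
        A = problem.A.to_dense()
        Qf = np.linalg.inv(problem.fc_prox(np.zeros(nx), np.ones(nx))[:, None] * 0 + np.eye(nx))
        # rebuild Qf, bf from the prox oracle: prox(v, m) = (Qf + diag m)^{-1}(m v - bf)
        m = np.ones(nx)
        p0 = problem.fc_prox(np.zeros(nx), m)
        J = np.column_stack(
            [problem.fc_prox(e, m) - p0 for e in np.eye(nx)]
        )  # J = (Qf + I)^{-1}
        Qf = np.linalg.inv(J) - np.eye(nx)
        bf = -np.linalg.inv(J) @ p0
        Hf = np.diag(cfg.Df_diag) - A.T @ A
        r = problem.constraint_residual(state.x, state.y)
        rhs = -(bf + A.T @ state.u + A.T @ (r) ) + Hf @ state.x + A.T @ A @ state.x
        oracle = np.linalg.solve(Qf + np.diag(cfg.Df_diag), np.diag(cfg.Df_diag) @ state.x - (bf + A.T @ (state.u + r)))
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_weakly_decreases_subproblem(self):
        rng = np.random.default_rng(3)
        problem, cfg, *_ = make_qp(rng, 4, 4, 3)
        state = AdmmState(
            x=rng.standard_normal(4), y=rng.standard_normal(4), u=rng.standard_normal(3)
        )
        A = problem.A.to_dense()
        Hf = np.diag(cfg.Df_diag) - A.T @ A

        def sub(x):
            r = problem.A(x) + problem.B(state.y) - problem.c
            return (
                problem.f_value(x)
                + x @ problem.A.adjoint(state.u)
                + 0.5 * r @ r
                + 0.5 * (x - state.x) @ Hf @ (x - state.x)
            )

        x_next = x_update(state, problem, cfg)
        assert sub(x_next) <= sub(state.x) + 1e-12


class TestYUpdate:
    def test_stationary(self):
        n = 3
        problem = identity_problem(n)
        y = np.array([0.3, -0.2, 1.0])
        state = AdmmState(x=y.copy(), y=y.copy(), u=np.zeros(n))
        cfg = StepConfig(sigma=2.0 * np.ones(n), Df_diag=2 * np.ones(n), Eg_diag=2.0 * np.ones(n))
        np.testing.assert_allclose(y_update(state, y.copy(), problem, cfg), y)

    def test_quantile_prox_perfect_fit(self):
        n = 4
        w = np.array([1.0, -1.0, 0.5, 2.0])
        problem = identity_problem(n)
        problem.gc_prox = lambda v, m: prox_quantile(v, w, 0.5, 1.0 / n, m)
        state = AdmmState(x=w.copy(), y=w.copy(), u=np.zeros(n))
        np.testing.assert_allclose(y_update(state, w.copy(), problem, unit_cfg(n)), w)

    def test_against_coordinatewise_golden_section(self):
        rng = np.random.default_rng(4)
        n = 3
        w = rng.standard_normal(n)
        q, a = 0.3, 0.5
        problem = identity_problem(n)
        problem.gc_prox = lambda v, m: prox_quantile(v, w, q, a, m)
        problem.gc_value = lambda y: a * float(quantile_loss(w - y, q).sum())
        state = AdmmState(
            x=rng.standard_normal(n), y=rng.standard_normal(n), u=rng.standard_normal(n)
        )
        x_next = rng.standard_normal(n)
        cfg = StepConfig(sigma=1.5 * np.ones(n), Df_diag=np.ones(n), Eg_diag=1.5 * np.ones(n))
        got = y_update(state, x_next, problem, cfg)
        for j in range(n):

            def sub(yj, j=j):
                r = x_next[j] - yj
                return (
                    a * quantile_loss(w[j] - yj, q)
                    + yj * (-state.u[j])
                    + 0.75 * r * r
                )

            ystar = minimize_scalar(sub, bounds=(-50, 50), method="bounded", options={"xatol": 1e-10}).x
            assert got[j] == pytest.approx(ystar, abs=1e-6)


class TestUUpdate:
    def test_direct_arithmetic(self):
        problem = identity_problem(2)
        cfg = StepConfig(sigma=2.0 * np.ones(2), Df_diag=np.ones(2), Eg_diag=np.ones(2))
        state = AdmmState(x=np.zeros(2), y=np.zeros(2), u=np.zeros(2))
        x1 = np.array([1.0, -1.0])  # residual x - y = (1, -1)
        np.testing.assert_allclose(u_update(state, x1, np.zeros(2), problem, cfg), [2.0, -2.0])

    def test_feasible_pair_leaves_u(self):
        problem = identity_problem(2)
        state = AdmmState(x=np.zeros(2), y=np.zeros(2), u=np.array([0.4, -0.7]))
        y = np.array([1.0, 2.0])
        np.testing.assert_allclose(u_update(state, y, y, problem, unit_cfg()), state.u)

    def test_dense_sigma(self):
        rng = np.random.default_rng(5)
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        problem = identity_problem(2)
        cfg = StepConfig(sigma=S, Df_diag=np.ones(2), Eg_diag=np.ones(2))
        state = AdmmState(x=np.zeros(2), y=np.zeros(2), u=rng.standard_normal(2))
        x1, y1 = rng.standard_normal(2), rng.standard_normal(2)
        np.testing.assert_allclose(
            u_update(state, x1, y1, problem, cfg), state.u + S @ (x1 - y1)
        )


class TestObjectives:
    def test_aug_lagrangian_feasible_equals_objective(self):
        rng = np.random.default_rng(6)
        problem, cfg, *_ = make_qp(rng, 3, 3, 2)
        # project a random x onto feasibility via y (need Ax + By = c): choose
        # y solving B y = c - A x (B square here)
        x = rng.standard_normal(3)
        B = problem.B.to_dense()
        y = np.linalg.lstsq(B, problem.c - problem.A(x), rcond=None)[0]
        u = rng.standard_normal(2)
        got = augmented_lagrangian(x, y, u, problem, cfg)
        assert got == pytest.approx(problem.f_value(x) + problem.g_value(y), abs=1e-10)

    def test_aug_lagrangian_pure_penalty(self):
        problem = identity_problem(2)
        x = np.array([1.0, 2.0])
        y = np.array([0.0, 0.0])
        u = np.array([0.3, -0.4])
        r = x - y
        expected = u @ r + 0.5 * r @ r
        assert augmented_lagrangian(x, y, u, problem, unit_cfg()) == pytest.approx(expected)

    def test_aug_lagrangian_term_recomputation(self):
        rng = np.random.default_rng(7)
        problem, cfg, *_ = make_qp(rng, 4, 3, 2)
        x, y, u = rng.standard_normal(4), rng.standard_normal(3), rng.standard_normal(2)
        r = problem.constraint_residual(x, y)
        expected = (
            problem.f_value(x) + problem.g_value(y) + u @ r + 0.5 * r @ (cfg.sigma * r)
        )
        assert augmented_lagrangian(x, y, u, problem, cfg) == pytest.approx(expected, rel=1e-12)

    def test_primal_residual(self):
        problem = identity_problem(2)
        cfg = StepConfig(sigma=4.0 * np.ones(2), Df_diag=np.ones(2), Eg_diag=np.ones(2))
        assert primal_residual(np.array([3.0, 4.0]), np.zeros(2), problem, cfg) == pytest.approx(10.0)
        y = np.array([1.0, 1.0])
        assert primal_residual(y, y, problem, cfg) == 0.0


class TestRunAdmm:
    def test_scalar_quadratic_converges_to_origin(self):
        problem = identity_problem(1)
        problem.fc_prox = lambda v, m: m * v / (1.0 + m)  # prox of x^2/2
        problem.fc_value = lambda x: 0.5 * float(x @ x)
        problem.gc_prox = lambda v, m: m * v / (1.0 + m)
        problem.gc_value = lambda y: 0.5 * float(y @ y)
        res = run_admm(problem, unit_cfg(1), T=500, init=(np.array([5.0]), np.array([-3.0]), np.array([1.0])))
        assert abs(res.x_bar[0]) < 0.05
        assert abs(res.x[0]) < 1e-8

    def test_lasso_matches_proximal_gradient_oracle(self):
        rng = np.random.default_rng(8)
        n, d = 8, 5
        Phi = rng.standard_normal((n, d))
        w = rng.standard_normal(n)
        lam = 0.3
        problem = SplitProblem(
            dim_x=d,
            dim_y=n,
            dim_c=n,
            A=LinearMap.from_matrix(Phi),
            B=LinearMap.scaled_identity(n, -1.0),
            fc_prox=lambda v, m: soft_threshold(v, lam / m),
            fc_value=lambda x: lam * float(np.abs(x).sum()),
            gc_prox=lambda v, m: (m * v + w) / (m + 1.0),
            gc_value=lambda y: 0.5 * float(((y - w) ** 2).sum()),
        )
        gamma = np.linalg.eigvalsh(Phi.T @ Phi).max() * 1.001
        cfg = StepConfig(sigma=np.ones(n), Df_diag=gamma * np.ones(d), Eg_diag=np.ones(n))
        res = run_admm(problem, cfg, T=4000)

        # oracle: proximal gradient (ISTA) on lam||x||_1 + 0.5||Phi x - w||^2
        L = np.linalg.eigvalsh(Phi.T @ Phi).max()
        x = np.zeros(d)
        for _ in range(20000):
            x = soft_threshold(x - Phi.T @ (Phi @ x - w) / L, lam / L)
        obj = lambda z: lam * np.abs(z).sum() + 0.5 * ((Phi @ z - w) ** 2).sum()
        assert obj(res.x) <= obj(x) + 1e-5

    def test_exact_fosp_is_fixed_point(self):
        # fc = ||.||_1, gc = 0.5||y||^2, constraint x = y; the triple
        # (0, 0, u) with |u_j| <= 1 satisfies -A'u in d f(0), -B'u = u = grad g(0)=0
        n = 3
        problem = identity_problem(n)
        problem.fc_prox = lambda v, m: soft_threshold(v, 1.0 / m)
        problem.fc_value = lambda x: float(np.abs(x).sum())
        problem.gc_prox = lambda v, m: m * v / (1.0 + m)
        problem.gc_value = lambda y: 0.5 * float(y @ y)
        u0 = np.array([0.5, -0.9, 0.0])  # -A'u = -u in [-1,1]^3 = subdiff; grad g(0) = 0 = -B'u requires u=0
        res = run_admm(problem, unit_cfg(n), T=3, init=(np.zeros(n), np.zeros(n), np.zeros(n)))
        np.testing.assert_allclose(res.x, 0.0, atol=1e-14)
        np.testing.assert_allclose(res.y, 0.0, atol=1e-14)
        # and with nonzero dual inside the subdifferential for the x block only
        res2 = run_admm(problem, unit_cfg(n), T=1, init=(np.zeros(n), np.zeros(n), u0))
        np.testing.assert_allclose(res2.x, 0.0, atol=1e-14)

    def test_dual_update_identity_every_iteration(self):
        rng = np.random.default_rng(9)
        problem, cfg, *_ = make_qp(rng, 4, 4, 3)
        us = []
        xs = []
        ys = []

        def spy(t, state):
            us.append(state.u.copy())
            xs.append(state.x.copy())
            ys.append(state.y.copy())
            return {}

        run_admm(problem, cfg, T=30, extra_log=spy)
        u_prev = np.zeros(3)
        for x, y, u in zip(xs, ys, us):
            r = problem.constraint_residual(x, y)
            np.testing.assert_array_equal(u, u_prev + cfg.sigma * r)
            u_prev = u

    def test_log_and_averages(self):
        rng = np.random.default_rng(10)
        problem, cfg, xs, ys, us = make_qp(rng, 3, 3, 2)
        T = 50
        snaps = []
        res = run_admm(problem, cfg, T=T, truth=(xs, ys), extra_log=lambda t, s: snaps.append(s.x.copy()) or {})
        assert len(res.log) == T
        assert list(res.log["t"]) == list(range(1, T + 1))
        np.testing.assert_allclose(res.x_bar, np.mean(snaps, axis=0), atol=1e-12)
        assert np.all(np.isfinite(res.log["rmse_x"]))

    def test_rejects_bad_T(self):
        problem = identity_problem(1)
        with pytest.raises(ConfigurationError):
            run_admm(problem, unit_cfg(1), T=0)


class TestStepConditions:
    def test_valid_config_passes(self):
        rng = np.random.default_rng(11)
        problem, cfg, *_ = make_qp(rng, 3, 3, 2)
        rep = verify_step_conditions(problem, cfg)
        assert rep.ok
        assert rep.min_eig_Hf >= -1e-8
        assert rep.min_eig_Df > 0

    def test_flags_insufficient_Hf_curvature(self):
        # Hf = 0 with a convex fd with positive-definite Hessian must be flagged
        n = 2
        problem = identity_problem(n)
        problem.fd_grad = lambda x: x  # fd = ||x||^2/2, Hessian = I
        cfg = StepConfig(sigma=np.ones(n), Df_diag=np.ones(n), Eg_diag=np.ones(n))
        rep = verify_step_conditions(
            problem,
            cfg,
            Hf=np.zeros((n, n)),
            fd_hessian=lambda x: np.eye(n),
            probes_x=[np.zeros(n)],
        )
        assert not rep.ok
        assert any("hess fd" in v for v in rep.violations)

    def test_quantile_app_Hf_dominates_concave_penalty(self):
        # the log-penalty's Hessian is bounded below by -lam/beta, so
        # Hf = sigma*(gamma I - Phi'Phi) >= hess fd on a d=20 instance
        from nladmm.quantile import QuantileProblemSpec, assemble_qr_problem
        from nladmm.synthetic import generate_qr_data

        data = generate_qr_data(n=30, d=20, s_star=3, noise="gaussian", seed=0)
        spec = QuantileProblemSpec(Phi=data.Phi, w=data.w, q=0.5, lam=0.1, beta=0.5, sigma=0.01)
        problem, cfg = assemble_qr_problem(spec)

        def fd_hess(x):
            ax = np.abs(x)
            return np.diag(-spec.lam * spec.beta / (spec.beta + ax) ** 2)

        rng = np.random.default_rng(1)
        rep = verify_step_conditions(
            problem,
            cfg,
            fd_hessian=fd_hess,
            probes_x=[rng.standard_normal(20) for _ in range(3)],
        )
        assert rep.ok
        assert all(e >= -1e-8 for e in rep.min_eig_Hf_minus_hess)
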