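"""Solver iterations: hand-evaluated steps, dual feasibility, baselines, oracles."""

import numpy as np
import pytest

import sparsesense as ss
from sparsesense import (
    AMParams,
    BOSParams,
    FiniteDifference,
    ReconProblem,
    SenseOperator,
    SolverParams,
    bb_stepsize,
    group_magnitude,
    objective,
    run_solver,
)

from conftest import random_complex


def _unitary_problem(n=16, lam=1e3):
    A = SenseOperator(np.ones((1, n, n), complex), np.ones((n, n)))
    D = FiniteDifference("tv", "periodic")
    y = np.zeros((1, n, n), complex)
    return ReconProblem(A=A, D=D, y=y, lam=lam)


class TestObjective:
    def test_zero_image(self, small_problem):
        expected = 0.5 * small_problem.lam * np.sum(np.abs(small_problem.y) ** 2)
        got = objective(small_problem, np.zeros((32, 32), complex))
        assert abs(got - expected) < 1e-9 * expected

    def test_exact_data_leaves_tv_only(self, rng):
        prob = _unitary_problem()
        x = random_complex(rng, (16, 16))
        prob2 = ReconProblem(A=prob.A, D=prob.D, y=prob.A.apply(x), lam=prob.lam)
        tv = float(np.sum(group_magnitude(prob.D.apply(x), prob.D.weights)))
        assert abs(objective(prob2, x) - tv) < 1e-9 * (1 + tv)

    def test_constant_image_has_no_tv_term(self):
        prob = _unitary_problem(lam=2.0)
        x = np.full((16, 16), 3.0, dtype=complex)
        expected = 0.5 * 2.0 * np.sum(np.abs(prob.A.apply(x)) ** 2)
        assert abs(objective(prob, x) - expected) < 1e-9 * expected


class TestBBStepsize:
    def test_unitary_operator_gives_one(self, rng):
        prob = _unitary_problem()
        x0 = random_complex(rng, (16, 16))
        x1 = x0 + random_complex(rng, (16, 16))
        assert abs(bb_stepsize(prob.A, x1, x0, 0.5) - 1.0) < 1e-12

    def test_rayleigh_quotient_of_eigenvector(self, small_ds):
        # single coil, unit sens: A^H A eigenvectors are the DFT modes with
        # eigenvalue mask(k); pick one sampled and one unsampled location
        ny = nx = 32
        A = SenseOperator(np.ones((1, ny, nx), complex), small_ds.mask)
        on = tuple(np.argwhere(small_ds.mask == 1)[0])
        off = tuple(np.argwhere(small_ds.mask == 0)[0])
        for loc, mu in ((on, 1.0), (off, 0.0)):
            e = np.zeros((ny, nx), complex)
            e[loc] = 1.0
            dx = ss.ifft2c(e)
            assert abs(bb_stepsize(A, dx, np.zeros_like(dx), 0.3) - mu) < 1e-12

    def test_degenerate_fallback(self, small_problem, rng):
        x = random_complex(rng, (32, 32))
        assert bb_stepsize(small_problem.A, x, x, 0.77) == 0.77


class TestSplittingSteps:
    def test_first_iterate_from_zero_state(self, small_problem):
        params = SolverParams(delta0=2.0)
        st0 = ss.SolverState(
            x=np.zeros((32, 32), complex),
            w=np.zeros((2, 32, 32), complex), delta=2.0)
        st1 = ss.fboss_step(small_problem, params, st0)
        expected = small_problem.A.adjoint(small_problem.y) / 2.0
        np.testing.assert_allclose(st1.x, expected, atol=1e-12)
        assert np.all(st1.w == 0)

    def test_first_iterate_as_printed_rule(self, small_problem):
        params = SolverParams(delta0=1.0, x_update_rule="as_printed")
        st0 = ss.SolverState(
            x=np.zeros((32, 32), complex),
            w=np.zeros((2, 32, 32), complex), delta=1.0)
        st1 = ss.fboss_step(small_problem, params, st0)
        expected = small_problem.lam * small_problem.A.adjoint(small_problem.y)
        np.testing.assert_allclose(st1.x, expected, atol=1e-9)

    def test_dual_feasibility_along_run(self, small_problem):
        params = SolverParams(max_iter=30)
        st = ss.initial_state(small_problem, params)
        for _ in range(30):
            st = ss.fboss_step(small_problem, params, st)
            assert np.max(group_magnitude(st.w)) <= 1.0 + 1e-12

    def test_fbosp_first_iterate_matches_fboss_exactly(self, small_problem):
        params = SolverParams()
        s1 = ss.initial_state(small_problem, params)
        s2 = ss.initial_state(small_problem, params)
        s1 = ss.fboss_step(small_problem, params, s1)
        s2 = ss.fbosp_step(small_problem, params, s2)
        np.testing.assert_allclose(s2.x, s1.x, rtol=0, atol=1e-10 * np.linalg.norm(s1.x))

    def test_moreau_equivalence_of_iterate_sequences(self, small_problem):
        # constant stepsize isolates the Moreau identity from BB round-off chaos
        params = SolverParams(max_iter=100, stepsize_mode="constant")
        s1 = ss.initial_state(small_problem, params)
        s2 = ss.initial_state(small_problem, params)
        for _ in range(100):
            s1 = ss.fboss_step(small_problem, params, s1)
            s2 = ss.fbosp_step(small_problem, params, s2)
            gap = np.linalg.norm(s1.x - s2.x) / np.linalg.norm(s1.x)
            assert gap < 1e-12


class TestBOS:
    def test_requires_periodic_tv(self, small_ds):
        A = SenseOperator(small_ds.sens, small_ds.mask)
        D = FiniteDifference("tgv2", "periodic")
        prob = ReconProblem(A=A, D=D, y=small_ds.kspace, lam=1e3)
        params = SolverParams()
        st = ss.initial_state(prob, params)
        with pytest.raises(ss.ConfigurationError):
            ss.bos_step(prob, params, BOSParams(), st)

    def test_x_solve_matches_dense_linear_solve(self, rng):
        # (rho D^T D + lam delta I) x = rhs by FFT vs a dense matrix solve, 8x8
        n = 8
        D = FiniteDifference("tv", "periodic")
        rho, lam, delta = 0.5, 1e3, 1.0
        basis = np.eye(n * n, dtype=complex)
        dtd = np.column_stack([
            D.adjoint(D.apply(basis[:, i].reshape(n, n))).ravel()
            for i in range(n * n)
        ])
        M = rho * dtd + lam * delta * np.eye(n * n)
        rhs = random_complex(rng, (n, n))
        dense = np.linalg.solve(M, rhs.ravel()).reshape(n, n)
        via_fft = np.fft.ifft2(np.fft.fft2(rhs) /
                               (rho * D.laplacian_symbol(n, n) + lam * delta))
        np.testing.assert_allclose(via_fft, dense, atol=1e-10)

    def test_objective_stationary_at_optimum(self):
        # start BOS from the FBOSS optimum (with the matched multiplier
        # w_bos = w_fboss / rho); objective must not increase over 10 steps
        ds = ss.make_dataset(ny=16, nx=16, ncoils=4, factor=2, snr_db=40.0, seed=1)
        A = SenseOperator(ds.sens, ds.mask)
        D = FiniteDifference("tv", "periodic")
        prob = ReconProblem(A=A, D=D, y=ds.kspace, lam=1e3)
        params = SolverParams(eps=1e-12, max_iter=20000)
        _, st_opt, rep = run_solver(prob, params, "fboss")
        assert rep.converged
        bosp = BOSParams()
        st = ss.SolverState(x=st_opt.x.copy(), w=st_opt.w / bosp.rho, delta=bosp.delta)
        obj0 = objective(prob, st.x)
        for _ in range(10):
            st = ss.bos_step(prob, params, bosp, st)
            assert objective(prob, st.x) <= obj0 * (1 + 1e-8)

    def test_shrink_of_zero_field(self):
        from sparsesense import group_shrink

        assert np.all(group_shrink(np.zeros((2, 4, 4), complex), 2.0) == 0)


class TestAM:
    def test_printed_schedules(self):
        am = AMParams()
        assert am.tau(0) == pytest.approx(0.2)
        assert am.tau(5) == pytest.approx(0.6)
        assert am.theta(0) == pytest.approx((0.5 - 5.0 / 15.0) / 0.2)

    def test_w_stays_in_unit_ball(self, small_problem):
        params = SolverParams(max_iter=20)
        am = AMParams()
        st = ss.initial_state(small_problem, params)
        st.v = st.x.copy()
        for _ in range(20):
            st = ss.am_step(small_problem, params, am, st)
            assert np.max(group_magnitude(st.w)) <= 1.0 + 1e-12

    def test_delta_update_is_bb_rule(self, small_problem):
        params = SolverParams()
        st = ss.initial_state(small_problem, params)
        st.v = st.x.copy()
        x_old, d_old = st.x.copy(), st.delta
        st1 = ss.am_step(small_problem, params, AMParams(), st)
        expected = bb_stepsize(small_problem.A, st1.x, x_old, d_old)
        assert st1.delta == pytest.approx(expected, rel=1e-12)

    def test_tv_only(self, small_ds):
        A = SenseOperator(small_ds.sens, small_ds.mask)
        D = FiniteDifference("tgv2", "neumann")
        prob = ReconProblem(A=A, D=D, y=small_ds.kspace, lam=1e3)
        params = SolverParams()
        st = ss.initial_state(prob, params)
        with pytest.raises(ss.ConfigurationError):
            ss.am_step(prob, params, AMParams(), st)


class TestRunSolver:
    def test_terminates_on_relative_change(self, small_problem):
        params = SolverParams(eps=1e-3, max_iter=400)
        _, _, rep = run_solver(small_problem, params, "fboss")
        assert rep.converged and rep.relative_change <= 1e-3
        assert list(rep.traces.columns[:3]) == ["iteration", "objective", "relative_change"]

    def test_noiseless_fully_sampled_single_coil_recovery(self):
        # lam = 1e6 makes the data term dominate; A is unitary, so the
        # reconstruction must match the truth almost exactly
        ds = ss.make_dataset(ny=32, nx=32, ncoils=1, factor=1.0, snr_db=None, seed=2)
        model = ss.SparseSenseModel.from_dataset(ds, lam=1e6)
        res = model.fit(method="fboss", max_iter=300)
        assert res.relative_error < 1e-3

    def test_unknown_algorithm_rejected(self, small_problem):
        with pytest.raises(ss.ConfigurationError):
            run_solver(small_problem, SolverParams(), "pdhg")

    def test_reports_metrics_with_reference(self, small_ds, small_problem):
        params = SolverParams(eps=1e-3, max_iter=200)
        _, _, rep = run_solver(small_problem, params, "fboss",
                               reference=small_ds.reference)
        assert rep.relative_error is not None and rep.relative_error >= 0
        assert {"psnr", "relative_error"} <= set(rep.traces.columns)
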