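"""Operator-splitting solvers for the SparseSENSE objective.

The model is ``min_x ||Dx||_1 + (lam/2) ||Ax - y||_2^2`` with ``A`` the
SENSE encoding operator and ``D`` a TV or TGV2 finite-difference operator
(``||.||_1`` is the isotropic group l1 norm).  Four iterations are provided:

* ``fboss`` — forward-backward operator splitting with groupwise shrinkage
  and a Barzilai-Borwein (BB) stepsize;
* ``fbosp`` — the same scheme with the dual update written as a groupwise
  projection; by the Moreau decomposition the two produce identical
  iterate sequences;
* ``bos``  — Bregman operator splitting baseline, whose x-update solves
  ``(rho D^T D + lam delta I) x = rhs`` by FFT diagonalisation (TV with
  periodic boundary only);
* ``am``   — alternating minimisation baseline with its printed stepsize
  schedules ``tau_k = 0.2 + 0.08 k`` and ``theta_k = (0.5 - 5/(15+k))/tau_k``.

Stepsizes: the BB rule ``delta = ||A dx||^2 / ||dx||^2`` is a Rayleigh
quotient of ``A^H A`` and therefore stays within its spectrum (at most 1
for normalised sensitivities); constant-stepsize mode keeps ``delta``
fixed, which is the regime in which the objective decreases monotonically
provided ``delta`` is at least the squared operator norm of ``A``.

The printed x-update coefficient "lam delta_k^-1" admits two parsings; the
default ``inverse_product`` rule uses ``1/(lam delta_k)`` together with the
gradient step ``z = x - delta^-1 A^H(Ax - y)``, the unique combination
whose fixed points satisfy the first-order optimality condition
``0 = D^T w + lam A^H (Ax - y)``.  The literal ``as_printed`` rule
(coefficient ``lam/delta`` on both steps) is provided for comparison; note
that the shared factor cancels in the fixed-point equation, so that mode
effectively solves the objective with unit data weight.

All solvers are deterministic; there is no randomness inside any step.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, DataError, DivergenceError
from .metrics import ReconReport, psnr as psnr_metric, relative_error
from .operators import FiniteDifference, SenseOperator, group_magnitude
from .prox import group_project, group_shrink, project_unit_ball

__all__ = [
    "ReconProblem",
    "SolverParams",
    "BOSParams",
    "AMParams",
    "SolverState",
    "objective",
    "bb_stepsize",
    "fboss_step",
    "fbosp_step",
    "bos_step",
    "am_step",
    "run_solver",
    "optimality_residual",
]

ALGORITHMS = ("fboss", "fbosp", "bos", "am")


@dataclass
class ReconProblem:
    """The data of one reconstruction: encoding A, transform D, k-space y, weight lam."""

    A: SenseOperator
    D: FiniteDifference
    y: np.ndarray
    lam: float = 1.0e3

    def __post_init__(self):
        if self.lam <= 0:
            raise ConfigurationError("data weight lam must be > 0")
        if self.y.shape != self.A.sens.shape:
            raise DataError("measured k-space shape inconsistent with encoding operator")


@dataclass
class SolverParams:
    """Knobs shared by FBOSS/FBOSP and the outer iteration loop."""

    gamma: float = 1.0
    delta0: float = 1.0
    eps: float = 5.0e-5
    max_iter: int = 500
    stepsize_mode: str = "bb"  # or "constant"
    x_update_rule: str = "inverse_product"  # or "as_printed"

    def __post_init__(self):
        if min(self.gamma, self.delta0, self.eps) <= 0 or self.max_iter < 1:
            raise ConfigurationError("solver parameters must be positive, max_iter >= 1")
        if self.stepsize_mode not in ("bb", "constant"):
            raise ConfigurationError(f"unknown stepsize mode {self.stepsize_mode!r}")
        if self.x_update_rule not in ("inverse_product", "as_printed"):
            raise ConfigurationError(f"unknown x_update_rule {self.x_update_rule!r}")


@dataclass
class BOSParams:
    rho: float = 0.5
    delta: float = 1.0

    def __post_init__(self):
        if self.rho <= 0 or self.delta <= 0:
            raise ConfigurationError("BOS parameters must be positive")


@dataclass
class AMParams:
    alpha: float = 1.0e2

    def tau(self, k: int) -> float:
        return 0.2 + 0.08 * k

    def theta(self, k: int) -> float:
        return (0.5 - 5.0 / (15.0 + k)) / self.tau(k)

    def __post_init__(self):
        if self.alpha <= 0:
            raise ConfigurationError("AM alpha must be positive")


@dataclass
class SolverState:
    """Iterates of one solver run; ``v`` is used only by the AM baseline."""

    x: np.ndarray
    w: np.ndarray
    delta: float = 1.0
    iter: int = 0
    v: np.ndarray | None = None
    history: list = field(default_factory=list)


def objective(problem: ReconProblem, x: np.ndarray) -> float:
    """``sum_pixels |Dx|_group + (lam/2) ||Ax - y||^2``."""
    Dx = problem.D.apply(x)
    tv_term = float(np.sum(group_magnitude(Dx, problem.D.weights)))
    r = problem.A.apply(x) - problem.y
    return tv_term + 0.5 * problem.lam * float(np.sum(np.abs(r) ** 2))


def bb_stepsize(A: SenseOperator, x_new: np.ndarray, x_old: np.ndarray,
                delta_prev: float) -> float:
    """Barzilai-Borwein stepsize ``||A dx||^2 / ||dx||^2`` (Rayleigh quotient).

    Falls back to ``delta_prev`` when the iterates coincide (0/0 in the
    printed formula).
    """
    dx = x_new - x_old
    den = float(np.real(np.vdot(dx, dx)))
    scale = max(float(np.real(np.vdot(x_new, x_new))), 1.0)
    if den < 1e-30 * scale:
        return delta_prev
    num = float(np.sum(np.abs(A.apply(dx)) ** 2))
    return num / den


def _grad_coeffs(problem: ReconProblem, params: SolverParams, delta: float):
    """(gradient-step factor, D^T w factor) for the configured x-update rule."""
    if params.x_update_rule == "inverse_product":
        return 1.0 / delta, 1.0 / (problem.lam * delta)
    return problem.lam / delta, problem.lam / delta


def _check_finite(x: np.ndarray, iteration: int, history: list) -> None:
    if not np.all(np.isfinite(x)):
        raise DivergenceError(iteration, history)


def _splitting_step(problem: ReconProblem, params: SolverParams,
                    state: SolverState, dual_update: str) -> SolverState:
    """Shared body of the FBOSS/FBOSP iteration (they differ only in how the
    dual variable is produced: shrinkage residual vs direct projection)."""
    A, D, y = problem.A, problem.D, problem.y
    g = params.gamma
    a_grad, a_dual = _grad_coeffs(problem, params, state.delta)

    z = state.x - a_grad * A.adjoint(A.apply(state.x) - y)
    v = g * state.w + D.apply(state.x)
    if dual_update == "shrink":
        s = group_shrink(v, g, D.weights)
        w_new = (v - s) / g
    else:
        w_new = group_project(v, g, D.weights)
    x_new = z - a_dual * D.adjoint(w_new)
    _check_finite(x_new, state.iter + 1, state.history)

    if params.stepsize_mode == "bb":
        delta_new = bb_stepsize(A, x_new, state.x, state.delta)
    else:
        delta_new = state.delta
    rel = _relative_change(x_new, state.x)
    hist = state.history + [{"iteration": state.iter + 1,
                             "objective": objective(problem, x_new),
                             "relative_change": rel}]
    return replace(state, x=x_new, w=w_new, delta=delta_new,
                   iter=state.iter + 1, history=hist)


def fboss_step(problem: ReconProblem, params: SolverParams,
               state: SolverState) -> SolverState:
    """One forward-backward operator splitting shrinkage (FBOSS) iteration."""
    return _splitting_step(problem, params, state, "shrink")


def fbosp_step(problem: ReconProblem, params: SolverParams,
               state: SolverState) -> SolverState:
    """One forward-backward operator splitting projection (FBOSP) iteration."""
    return _splitting_step(problem, params, state, "project")


def bos_step(problem: ReconProblem, params: SolverParams, bos: BOSParams,
             state: SolverState) -> SolverState:
    """One Bregman operator splitting iteration (fixed delta).

    The x-update solves ``(rho D^T D + lam delta I) x = rho D^T (s - w) +
    lam z`` exactly by FFT, which requires the periodic-TV transform whose
    ``D^T D`` is diagonalised by the DFT.
    """
    A, D, y = problem.A, problem.D, problem.y
    if D.kind != "tv" or D.boundary != "periodic":
        raise ConfigurationError(
            "BOS requires the periodic-boundary TV transform (FFT-diagonalizable D^T D)"
        )
    lam, rho, delta = problem.lam, bos.rho, bos.delta
    ny, nx = state.x.shape

    z = delta * state.x - A.adjoint(A.apply(state.x) - y)
    s = group_shrink(state.w + D.apply(state.x), 1.0 / rho, D.weights)
    rhs = rho * D.adjoint(s - state.w) + lam * z
    denom = rho * D.laplacian_symbol(ny, nx) + lam * delta
    x_new = np.fft.ifft2(np.fft.fft2(rhs) / denom)
    _check_finite(x_new, state.iter + 1, state.history)
    w_new = state.w + D.apply(x_new) - s

    rel = _relative_change(x_new, state.x)
    hist = state.history + [{"iteration": state.iter + 1,
                             "objective": objective(problem, x_new),
                             "relative_change": rel}]
    return replace(state, x=x_new, w=w_new, delta=delta,
                   iter=state.iter + 1, history=hist)


def am_step(problem: ReconProblem, params: SolverParams, am: AMParams,
            state: SolverState) -> SolverState:
    """One alternating-minimisation iteration with the printed schedules.

    The denoising split variable ``v`` (an image) rides along in the state;
    ``w`` is projected onto the unit group ball each iteration and the
    stepsize delta is refreshed with the same BB rule as FBOSS/FBOSP.
    """
    A, D, y = problem.A, problem.D, problem.y
    if D.kind != "tv":
        raise ConfigurationError("the AM baseline is TV-specific")
    lam, alpha = problem.lam, am.alpha
    k = state.iter
    tau, theta = am.tau(k), am.theta(k)
    v_old = state.v if state.v is not None else state.x

    z = state.delta * state.x - A.adjoint(A.apply(state.x) - y)
    w_new = project_unit_ball(state.w + tau * D.apply(v_old), D.weights)
    v_new = (v_old + 2 * alpha * theta * state.x - theta * D.adjoint(w_new)) / (
        1.0 + 2 * alpha * theta
    )
    x_new = (2 * alpha * v_new + lam * z) / (lam * state.delta + 2 * alpha)
    _check_finite(x_new, k + 1, state.history)
    delta_new = bb_stepsize(A, x_new, state.x, state.delta)

    rel = _relative_change(x_new, state.x)
    hist = state.history + [{"iteration": k + 1,
                             "objective": objective(problem, x_new),
                             "relative_change": rel}]
    return replace(state, x=x_new, w=w_new, v=v_new, delta=delta_new,
                   iter=k + 1, history=hist)


def _relative_change(x_new: np.ndarray, x_old: np.ndarray) -> float:
    num = float(np.linalg.norm(x_new - x_old))
    den = float(np.linalg.norm(x_new))
    return num / den if den > 0 else (0.0 if num == 0 else np.inf)


def initial_state(problem: ReconProblem, params: SolverParams,
                  x0: np.ndarray | None = None) -> SolverState:
    """Default initialisation: zero-filled recon ``x0 = A^H y``, ``w0 = 0``, ``delta0``."""
    x = problem.A.adjoint(problem.y) if x0 is None else np.asarray(x0, dtype=complex)
    w = np.zeros((problem.D.nfields,) + x.shape, dtype=complex)
    return SolverState(x=x, w=w, delta=params.delta0, iter=0)


def optimality_residual(problem: ReconProblem, state: SolverState) -> float:
    """Normalised first-order residual ``||D^T w + lam A^H(Ax - y)|| / (lam ||A^H y||)``."""
    A, D, y, lam = problem.A, problem.D, problem.y, problem.lam
    res = D.adjoint(state.w) + lam * A.adjoint(A.apply(state.x) - y)
    return float(np.linalg.norm(res) / (lam * np.linalg.norm(A.adjoint(y))))


def run_solver(problem: ReconProblem, params: SolverParams | None = None,
               algo: str = "fboss", *, bos: BOSParams | None = None,
               am: AMParams | None = None, x0: np.ndarray | None = None,
               reference: np.ndarray | None = None):
    """Iterate the chosen algorithm until the relative change drops below eps.

    Returns ``(x, state, report)`` where ``report`` is a
    :class:`~sparsesense.metrics.ReconReport` with per-iteration traces
    (objective, relative change, cumulative seconds, and PSNR / relative
    error when a reference image is supplied).
    """
    import pandas as pd

    if algo not in ALGORITHMS:
        raise ConfigurationError(f"unknown algorithm {algo!r}; choose from {ALGORITHMS}")
    params = params or SolverParams()
    state = initial_state(problem, params, x0)
    if algo == "bos":
        bos = bos or BOSParams()
    if algo == "am":
        am = am or AMParams()

    t0 = time.perf_counter()
    converged = False
    for _ in range(params.max_iter):
        if algo == "fboss":
            state = fboss_step(problem, params, state)
        elif algo == "fbosp":
            state = fbosp_step(problem, params, state)
        elif algo == "bos":
            state = bos_step(problem, params, bos, state)
        else:
            state = am_step(problem, params, am, state)
        row = state.history[-1]
        row["seconds"] = time.perf_counter() - t0
        if reference is not None:
            row["psnr"] = psnr_metric(state.x, reference)
            row["relative_error"] = relative_error(state.x, reference)
        if row["relative_change"] <= params.eps:
            converged = True
            break

    last = state.history[-1] if state.history else {
        "objective": objective(problem, state.x), "relative_change": np.inf}
    report = ReconReport(
        algo=algo,
        iterations=state.iter,
        converged=converged,
        objective=float(last["objective"]),
        relative_change=float(last["relative_change"]),
        elapsed_seconds=time.perf_counter() - t0,
        psnr=(psnr_metric(state.x, reference) if reference is not None else None),
        relative_error=(relative_error(state.x, reference) if reference is not None else None),
        params={
            "algo": algo, "lam": problem.lam, "gamma": params.gamma,
            "delta0": params.delta0, "eps": params.eps, "max_iter": params.max_iter,
            "stepsize_mode": params.stepsize_mode, "x_update_rule": params.x_update_rule,
            "reg": problem.D.kind, "boundary": problem.D.boundary,
            **({"rho": bos.rho, "bos_delta": bos.delta} if algo == "bos" else {}),
            **({"alpha": am.alpha} if algo == "am" else {}),
        },
        traces=pd.DataFrame(state.history),
    )
    return state.x, state, report
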