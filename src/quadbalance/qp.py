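"""Dense convex quadratic programming with KKT verification.

Solves  min 1/2 x^T H x + g^T x  subject to

    A_eq x  = b_eq
    A_ge x >= b_ge
    lb <= x <= ub

for symmetric positive-(semi)definite H.  The solver runs SLSQP to locate
the optimum, then refines it with a primal active-set method whose
equality-constrained subproblems are solved exactly through the KKT
linear system, so equality residuals end up at linear-solve precision
rather than at the iterative solver's tolerance.  Every solution can be
verified against the first-order optimality conditions by
:func:`kkt_check`, which estimates multipliers independently via bounded
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear, minimize

_FEAS_TOL = 1e-8
_ACTIVE_TOL = 1e-7


@dataclass
class QpProblem:
    """A convex QP in standard form; missing blocks may be None/empty."""

    H: np.ndarray
    g: np.ndarray | None = None
    A_eq: np.ndarray | None = None
    b_eq: np.ndarray | None = None
    A_ge: np.ndarray | None = None
    b_ge: np.ndarray | None = None
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        n = self.H.shape[0]
        if self.H.shape != (n, n):
            raise ValueError("H must be square")
        if not np.allclose(self.H, self.H.T, atol=1e-10):
            raise ValueError("H must be symmetric")
        self.g = np.zeros(n) if self.g is None else np.asarray(self.g, dtype=float)
        for name in ("A_eq", "A_ge"):
            A = getattr(self, name)
            if A is not None:
                setattr(self, name, np.atleast_2d(np.asarray(A, dtype=float)))
        for name in ("b_eq", "b_ge"):
            b = getattr(self, name)
            if b is not None:
                b = np.atleast_1d(np.asarray(b, dtype=float))
                if not np.all(np.isfinite(b)):
                    raise ValueError(f"{name} must be finite")
                setattr(self, name, b)
        self.lb = np.full(n, -np.inf) if self.lb is None else np.asarray(self.lb, dtype=float)
        self.ub = np.full(n, np.inf) if self.ub is None else np.asarray(self.ub, dtype=float)
        if np.any(self.lb > self.ub):
            raise ValueError("lower bounds exceed upper bounds")

    @property
    def n(self) -> int:
        return self.H.shape[0]

    def objective(self, x: np.ndarray) -> float:
        return float(0.5 * x @ self.H @ x + self.g @ x)

    def max_violation(self, x: np.ndarray) -> float:
        v = 0.0
        if self.A_eq is not None:
            v = max(v, float(np.max(np.abs(self.A_eq @ x - self.b_eq))))
        if self.A_ge is not None:
            v = max(v, float(np.max(np.maximum(self.b_ge - self.A_ge @ x, 0.0))))
        v = max(v, float(np.max(np.maximum(self.lb - x, 0.0), initial=0.0)))
        v = max(v, float(np.max(np.maximum(x - self.ub, 0.0), initial=0.0)))
        return v


@dataclass
class QpSolution:
    x: np.ndarray
    status: str  # "optimal" | "infeasible"
    objective: float
    eq_residual: float
    max_violation: float
    kkt_residual: float = np.nan
    iterations: int = 0
    message: str = ""


def _inequality_rows(prob: QpProblem) -> tuple[np.ndarray, np.ndarray]:
    """All inequality constraints in '>= b' form, bounds included."""
    n = prob.n
    blocks, rhs = [], []
    if prob.A_ge is not None:
        blocks.append(prob.A_ge)
        rhs.append(prob.b_ge)
    finite_lb = np.isfinite(prob.lb)
    if np.any(finite_lb):
        I = np.eye(n)[finite_lb]
        blocks.append(I)
        rhs.append(prob.lb[finite_lb])
    finite_ub = np.isfinite(prob.ub)
    if np.any(finite_ub):
        I = -np.eye(n)[finite_ub]
        blocks.append(I)
        rhs.append(-prob.ub[finite_ub])
    if not blocks:
        return np.zeros((0, n)), np.zeros(0)
    return np.vstack(blocks), np.concatenate(rhs)


def _slsqp_start(prob: QpProblem, x0: np.ndarray | None) -> np.ndarray:
    if x0 is not None:
        return np.clip(np.asarray(x0, dtype=float), prob.lb, prob.ub)
    lo = np.where(np.isfinite(prob.lb), prob.lb, 0.0)
    hi = np.where(np.isfinite(prob.ub), prob.ub, 1.0)
    return lo + 0.25 * (hi - lo)


def _run_slsqp(prob: QpProblem, x0: np.ndarray) -> np.ndarray:
    cons = []
    if prob.A_eq is not None:
        cons.append({"type": "eq",
                     "fun": lambda x, A=prob.A_eq, b=prob.b_eq: A @ x - b,
                     "jac": lambda x, A=prob.A_eq: A})
    if prob.A_ge is not None:
        cons.append({"type": "ineq",
                     "fun": lambda x, A=prob.A_ge, b=prob.b_ge: A @ x - b,
                     "jac": lambda x, A=prob.A_ge: A})
    res = minimize(prob.objective, x0, jac=lambda x: prob.H @ x + prob.g,
                   bounds=list(zip(prob.lb, prob.ub)), constraints=cons,
                   method="SLSQP", options={"maxiter": 800, "ftol": 1e-14})
    return np.clip(res.x, prob.lb, prob.ub)


def _solve_eqp(prob: QpProblem, C: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of min 1/2 x'Hx + g'x s.t. Cx = d via the KKT system."""
    n, m = prob.n, C.shape[0]
    K = np.zeros((n + m, n + m))
    K[:n, :n] = prob.H
    K[:n, n:] = C.T
    K[n:, :n] = C
    rhs = np.concatenate([-prob.g, d])
    sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    return sol[:n], sol[n:]


def solve_qp(prob: QpProblem, x0: np.ndarray | None = None,
             max_iter: int = 300) -> QpSolution:
    """Solve a convex QP: SLSQP search plus active-set polish.

    Returns status ``infeasible`` when no point satisfies the constraints
    to within 1e-6 (as judged by the SLSQP search's best point).
    """
    A_in, b_in = _inequality_rows(prob)
    x = _run_slsqp(prob, _slsqp_start(prob, x0))

    if prob.max_violation(x) > 1e-6:
        # one retry from a different start before declaring infeasibility
        x_retry = _run_slsqp(prob, np.clip(np.zeros(prob.n), prob.lb, prob.ub))
        if prob.max_violation(x_retry) < prob.max_violation(x):
            x = x_retry
        if prob.max_violation(x) > 1e-6:
            return QpSolution(x=x, status="infeasible", objective=prob.objective(x),
                              eq_residual=_eq_residual(prob, x),
                              max_violation=prob.max_violation(x),
                              message="constraints incompatible at SLSQP best point")

    x, its, msg = _active_set_refine(prob, A_in, b_in, x, max_iter)
    return QpSolution(x=x, status="optimal", objective=prob.objective(x),
                      eq_residual=_eq_residual(prob, x),
                      max_violation=prob.max_violation(x),
                      kkt_residual=kkt_check(prob, x).stationarity,
                      iterations=its, message=msg)


def _eq_residual(prob: QpProblem, x: np.ndarray) -> float:
    if prob.A_eq is None:
        return 0.0
    return float(np.max(np.abs(prob.A_eq @ x - prob.b_eq)))


def _active_set_refine(prob: QpProblem, A_in: np.ndarray, b_in: np.ndarray,
                       x: np.ndarray, max_iter: int) -> tuple[np.ndarray, int, str]:
    """Primal active-set iteration started from a near-optimal point."""
    n_eq = 0 if prob.A_eq is None else prob.A_eq.shape[0]
    slack = A_in @ x - b_in if len(b_in) else np.zeros(0)
    working = set(np.flatnonzero(slack <= _ACTIVE_TOL).tolist())

    for it in range(max_iter):
        rows = sorted(working)
        if n_eq:
            C = np.vstack([prob.A_eq, A_in[rows]]) if rows else prob.A_eq
            d = np.concatenate([prob.b_eq, b_in[rows]]) if rows else prob.b_eq
        elif rows:
            C, d = A_in[rows], b_in[rows]
        else:
            C = np.zeros((0, prob.n))
            d = np.zeros(0)
        x_star, lam = _solve_eqp(prob, C, d)
        p = x_star - x

        if np.max(np.abs(p), initial=0.0) < 1e-11:
            # at the EQP optimum: check multiplier signs of working ineqs
            if rows:
                mu = lam[n_eq:]
                j = int(np.argmin(mu))
                if mu[j] < -1e-9:
                    working.discard(rows[j])
                    continue
            return x, it, "active-set optimum"

        # step toward x_star, blocked by inactive inequalities
        alpha, blocker = 1.0, None
        if len(b_in):
            inactive = np.setdiff1d(np.arange(len(b_in)), rows, assume_unique=False)
            Ap = A_in[inactive] @ p
            decreasing = Ap < -1e-13
            if np.any(decreasing):
                idx = inactive[decreasing]
                room = A_in[idx] @ x - b_in[idx]
                steps = room / -(A_in[idx] @ p)
                k = int(np.argmin(steps))
                if steps[k] < alpha:
                    alpha = max(steps[k], 0.0)
                    blocker = int(idx[k])
        x = x + alpha * p
        if blocker is not None:
            working.add(blocker)
    return x, max_iter, "active-set iteration limit"


@dataclass
class KktReport:
    """Solver-independent first-order optimality diagnostics."""

    stationarity: float
    primal_feasibility: float
    complementarity: float
    dual_feasibility: float
    passed: bool = field(default=False)


def kkt_check(prob: QpProblem, x: np.ndarray, tol: float = 1e-6,
              active_tol: float = 1e-6) -> KktReport:
    """Verify stationarity/feasibility/complementarity at ``x``.

    Multipliers are estimated by bounded least squares (free for
    equalities, nonnegative for active inequalities and bounds), entirely
    independent of how ``x`` was produced.
    """
    x = np.asarray(x, dtype=float)
    grad = prob.H @ x + prob.g
    A_in, b_in = _inequality_rows(prob)
    slack = A_in @ x - b_in if len(b_in) else np.zeros(0)
    active = np.flatnonzero(slack <= active_tol)

    blocks, lower = [], []
    if prob.A_eq is not None:
        blocks.append(prob.A_eq.T)
        lower.extend([-np.inf] * prob.A_eq.shape[0])
    if len(active):
        blocks.append(A_in[active].T)
        lower.extend([0.0] * len(active))
    if blocks:
        M = np.hstack(blocks)
        res = lsq_linear(M, grad, bounds=(np.array(lower), np.inf))
        stationarity = float(np.max(np.abs(M @ res.x - grad)))
        dual = 0.0  # bounds enforce nonnegativity exactly
        comp = float(np.max(np.abs(res.x[len(lower) - len(active):] * slack[active]))) \
            if len(active) else 0.0
    else:
        stationarity = float(np.max(np.abs(grad), initial=0.0))
        dual = 0.0
        comp = 0.0

    primal = prob.max_violation(x)
    report = KktReport(stationarity=stationarity, primal_feasibility=primal,
                       complementarity=comp, dual_feasibility=dual)
    report.passed = (stationarity <= tol and primal <= tol and comp <= tol)
    return report
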