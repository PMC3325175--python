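"""The five static optimal-control formulations of quadrupedal balance.

All formulations share the quasi-static muscle-to-wrench model and differ
in cost and task constraint:

* ``solve_mme``  — minimum muscle effort (sum squared activation) subject
  to five CoM wrench equalities (yaw free), activation in [0, 1] and
  per-limb vertical ground-reaction force >= 0.
* ``solve_mmm``  — same constraints, cost weighted by muscle mass (a
  stand-in for metabolic energy: fibre count scales with mass).
* ``solve_mpe``  — minimum effort subject to a CoP-displacement equality
  (with a 30 N net-vertical-force companion constraint that makes the
  CoP equality linear); CoM horizontal forces and moments are free.
* ``solve_synergy`` — MMe's constraints with activation restricted to
  nonnegative combinations of five per-limb muscle synergies; cost is
  either muscle effort ||W c||^2 (SMe) or synergy effort ||c||^2 (SMc).
* ``solve_mme_zero_endpoint_moment`` — MMe plus three endpoint-moment
  equalities per hindlimb.

Infeasible problems can be retried through :func:`relax_and_resolve`,
which converts the vertical-force inequalities into a smooth one-sided
quadratic penalty while keeping the CoM equalities hard.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .qp import KktReport, QpProblem, QpSolution, kkt_check, solve_qp
from .quadruped import N_ACT, QuadrupedModel, cop_of_solution
from .synergies import SynergySet
from .targets import ComWrenchTarget, CopTarget

#: rows of the CoM wrench constrained by the CoM-target models (yaw free)
COM_EQ_ROWS = (0, 1, 2, 3, 4)

_SME_RIDGE = 1e-10


@dataclass
class OptimizationResult:
    """Solution of one formulation at one condition."""

    model: str
    activation: np.ndarray
    achieved_wrench: np.ndarray
    limb_forces: np.ndarray  # 4x3 N
    cop_cm: np.ndarray  # 2-vector, cm, absolute
    effort: float  # sum squared activation
    energy: float  # mass-weighted sum squared activation (g)
    status: str  # "optimal" | "relaxed" | "infeasible"
    solve_time_s: float
    constraint_residual: float
    kkt: KktReport | None = None
    synergy_coeffs: np.ndarray | None = None
    direction_deg: float | None = None

    @property
    def converged(self) -> bool:
        return self.status in ("optimal", "relaxed")


def _mass_vector(model: QuadrupedModel) -> np.ndarray:
    return np.concatenate([limb.masses for limb in model.limbs])


def _finish(model: QuadrupedModel, name: str, x: np.ndarray, status: str,
            residual: float, t0: float, kkt: KktReport | None,
            c: np.ndarray | None = None,
            direction: float | None = None) -> OptimizationResult:
    forces = model.limb_forces(x)
    try:
        cop = cop_of_solution(model, x) * 100.0
    except ValueError:
        cop = np.full(2, np.nan)
    masses = _mass_vector(model)
    return OptimizationResult(
        model=name, activation=x,
        achieved_wrench=model.wrench_map @ x,
        limb_forces=forces, cop_cm=cop,
        effort=float(x @ x), energy=float(masses @ (x * x)),
        status=status, solve_time_s=time.perf_counter() - t0,
        constraint_residual=residual, kkt=kkt, synergy_coeffs=c,
        direction_deg=direction,
    )


def _com_problem(model: QuadrupedModel, target: ComWrenchTarget,
                 weights: np.ndarray | None = None,
                 extra_eq: tuple[np.ndarray, np.ndarray] | None = None) -> QpProblem:
    A_eq = model.wrench_map[list(COM_EQ_ROWS)]
    b_eq = target.equality_rhs
    if extra_eq is not None:
        A_eq = np.vstack([A_eq, extra_eq[0]])
        b_eq = np.concatenate([b_eq, extra_eq[1]])
    H = np.diag(2.0 * (weights if weights is not None else np.ones(N_ACT)))
    return QpProblem(H=H, A_eq=A_eq, b_eq=b_eq,
                     A_ge=model.vertical_force_rows(), b_ge=np.zeros(4),
                     lb=np.zeros(N_ACT), ub=np.ones(N_ACT))


def solve_mme(model: QuadrupedModel, target: ComWrenchTarget) -> OptimizationResult:
    """Minimum-effort control of CoM force and moment (model MMe)."""
    t0 = time.perf_counter()
    prob = _com_problem(model, target)
    sol = solve_qp(prob)
    return _qp_result(model, "MMe", prob, sol, t0, target.direction_deg)


def solve_mmm(model: QuadrupedModel, target: ComWrenchTarget) -> OptimizationResult:
    """Minimum-energy control: effort weighted by muscle mass (model MMm)."""
    t0 = time.perf_counter()
    masses = _mass_vector(model)
    if np.any(masses <= 0):
        raise ValueError("muscle masses must be positive")
    prob = _com_problem(model, target, weights=masses)
    sol = solve_qp(prob)
    return _qp_result(model, "MMm", prob, sol, t0, target.direction_deg)


def solve_mpe(model: QuadrupedModel, target: CopTarget) -> OptimizationResult:
    """Minimum-effort control of CoP location (model MPe).

    The CoP equality  sum_i (p_i - cop*) Fz_i = 0  is linear in activation
    once the net vertical force is pinned (companion constraint); the
    returned solution's nonlinearly recomputed CoP matches the target.
    """
    t0 = time.perf_counter()
    vf_rows = model.vertical_force_rows()  # 4x124
    p = model.endpoints[:, :2]  # m
    centroid = p.mean(axis=0)
    cop_star = centroid + target.displacement_m
    # rows: sum_i (p_i - cop*)_k * Fz_i(x) = 0 for k in {x, y}; sum_i Fz_i = Fv
    A_cop = (p - cop_star).T @ vf_rows  # 2x124
    A_eq = np.vstack([A_cop, vf_rows.sum(axis=0)])
    b_eq = np.array([0.0, 0.0, target.f_vertical])
    prob = QpProblem(H=2.0 * np.eye(N_ACT), A_eq=A_eq, b_eq=b_eq,
                     A_ge=vf_rows, b_ge=np.zeros(4),
                     lb=np.zeros(N_ACT), ub=np.ones(N_ACT))
    sol = solve_qp(prob)
    return _qp_result(model, "MPe", prob, sol, t0, target.direction_deg)


def solve_synergy(model: QuadrupedModel, target: ComWrenchTarget,
                  synergies: SynergySet,
                  cost: str = "muscle_effort") -> OptimizationResult:
    """Synergy-constrained CoM control (models SMe and SMc).

    Optimizes over per-limb synergy coefficients c >= 0 with activation
    e = W c; ``cost`` selects muscle effort ||W c||^2 (SMe) or synergy
    effort ||c||^2 (SMc).  Activation upper bounds apply to e = W c.
    """
    if cost not in ("muscle_effort", "synergy_effort"):
        raise ValueError("cost must be 'muscle_effort' or 'synergy_effort'")
    name = "SMe" if cost == "muscle_effort" else "SMc"
    t0 = time.perf_counter()
    Wb = synergies.block_matrix()  # 124 x (4*k)
    nc = Wb.shape[1]
    A_eq = model.wrench_map[list(COM_EQ_ROWS)] @ Wb
    vf_rows = model.vertical_force_rows() @ Wb
    # e = Wc <= 1 (Wc >= 0 holds since W >= 0, c >= 0)
    A_ge = np.vstack([vf_rows, -Wb])
    b_ge = np.concatenate([np.zeros(4), -np.ones(N_ACT)])
    if cost == "muscle_effort":
        H = 2.0 * (Wb.T @ Wb + _SME_RIDGE * np.eye(nc))
    else:
        H = 2.0 * np.eye(nc)
    prob = QpProblem(H=H, A_eq=A_eq, b_eq=target.equality_rhs,
                     A_ge=A_ge, b_ge=b_ge,
                     lb=np.zeros(nc), ub=np.full(nc, np.inf))
    sol = solve_qp(prob)
    x = Wb @ sol.x
    if sol.status != "optimal":
        return _finish(model, name, x, "infeasible", sol.max_violation, t0,
                       None, c=sol.x, direction=target.direction_deg)
    kkt = kkt_check(prob, sol.x)
    return _finish(model, name, x, "optimal", sol.eq_residual, t0, kkt,
                   c=sol.x, direction=target.direction_deg)


def solve_mme_zero_endpoint_moment(model: QuadrupedModel,
                                   target: ComWrenchTarget) -> OptimizationResult:
    """MMe with hindlimb endpoint moments constrained to zero.

    Forelimb struts carry no endpoint moments, so only the two hindlimbs
    contribute the extra 3 equalities each.  Non-convergence is reported
    as status ``infeasible``, never masked.
    """
    t0 = time.perf_counter()
    rows, rhs = [], []
    for i, limb in enumerate(model.limbs):
        if limb.kind != "hindlimb":
            continue
        block = np.zeros((3, N_ACT))
        block[:, model.limb_slice(i)] = model.limb_maps[i].moment_rows
        rows.append(block)
        rhs.append(np.zeros(3))
    extra = (np.vstack(rows), np.concatenate(rhs)) if rows else None
    prob = _com_problem(model, target, extra_eq=extra)
    sol = solve_qp(prob)
    return _qp_result(model, "MMe0", prob, sol, t0, target.direction_deg)


def _qp_result(model: QuadrupedModel, name: str, prob: QpProblem,
               sol: QpSolution, t0: float,
               direction: float | None) -> OptimizationResult:
    if sol.status != "optimal":
        return _finish(model, name, sol.x, "infeasible", sol.max_violation,
                       t0, None, direction=direction)
    kkt = kkt_check(prob, sol.x)
    return _finish(model, name, sol.x, "optimal", sol.eq_residual, t0, kkt,
                   direction=direction)


def relax_and_resolve(model: QuadrupedModel, prob: QpProblem,
                      name: str = "relaxed", penalty_weight: float = 1e3,
                      direction: float | None = None) -> OptimizationResult:
    """Re-solve with vertical-force inequalities as a quadratic penalty.

    The per-limb VF >= 0 rows move into the objective as
    ``penalty_weight * sum max(0, -VF_i)^2`` while equalities stay hard.
    The result is flagged ``relaxed`` and is excluded from assessment
    aggregates by default.  Raises if the penalized problem still fails.
    """
    A_ge = prob.A_ge if prob.A_ge is not None else np.zeros((0, prob.n))
    b_ge = prob.b_ge if prob.b_ge is not None else np.zeros(0)
    t0 = time.perf_counter()

    def fun(x: np.ndarray) -> float:
        viol = np.maximum(b_ge - A_ge @ x, 0.0)
        return prob.objective(x) + penalty_weight * float(viol @ viol)

    def jac(x: np.ndarray) -> np.ndarray:
        viol = np.maximum(b_ge - A_ge @ x, 0.0)
        return prob.H @ x + prob.g - 2.0 * penalty_weight * (A_ge.T @ viol)

    cons = []
    if prob.A_eq is not None:
        cons.append({"type": "eq",
                     "fun": lambda x: prob.A_eq @ x - prob.b_eq,
                     "jac": lambda x: prob.A_eq})
    x0 = np.clip(np.full(prob.n, 0.25), prob.lb, prob.ub)
    res = minimize(fun, x0, jac=jac, bounds=list(zip(prob.lb, prob.ub)),
                   constraints=cons, method="SLSQP",
                   options={"maxiter": 1000, "ftol": 1e-14})
    x = np.clip(res.x, prob.lb, prob.ub)
    eq_res = 0.0 if prob.A_eq is None else float(np.max(np.abs(prob.A_eq @ x - prob.b_eq)))
    if eq_res > 1e-5:
        raise RuntimeError(
            f"relaxation failed: equality residual {eq_res:.2e} after penalty solve")
    if x.shape[0] == N_ACT:
        return _finish(model, name, x, "relaxed", eq_res, t0, None,
                       direction=direction)
    # synergy-space problem: report in coefficient space
    return OptimizationResult(model=name, activation=x,
                              achieved_wrench=np.full(6, np.nan),
                              limb_forces=np.full((4, 3), np.nan),
                              cop_cm=np.full(2, np.nan),
                              effort=float(x @ x), energy=np.nan,
                              status="relaxed",
                              solve_time_s=time.perf_counter() - t0,
                              constraint_residual=eq_res, synergy_coeffs=x,
                              direction_deg=direction)
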