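"""Muscle synergies derived from endpoint ground-reaction force vectors.

Each synergy is a fixed 31-element activation pattern recruited by a
single nonnegative coefficient.  Synergy patterns are derived from the
limb model itself: the minimum-effort activation that reproduces a given
endpoint force vector.  The same five patterns are reused in every limb
and every stance configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .limb import N_MUSCLES, MuscleWrenchMap
from .qp import QpProblem, solve_qp

N_SYNERGIES = 5


@dataclass
class SynergyForceVector:
    """A 3-D endpoint ground-reaction force target (N) for one synergy."""

    force: np.ndarray
    label: int = 1

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if self.force.shape != (3,):
            raise ValueError("synergy force vector must be a 3-vector")
        if np.linalg.norm(self.force) <= 0:
            raise ValueError("synergy force vector must be nonzero")


@dataclass
class SynergySet:
    """31 x k synergy weighting matrix W shared across the four limbs."""

    W: np.ndarray
    force_vectors: list[SynergyForceVector] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape[0] != N_MUSCLES:
            raise ValueError(f"W must have {N_MUSCLES} rows")
        if np.any(self.W < -1e-12) or np.any(self.W > 1 + 1e-12):
            raise ValueError("W elements must lie in [0, 1]")
        if np.any(np.all(self.W == 0, axis=0)):
            raise ValueError("W columns must be nonzero")

    @property
    def n_synergies(self) -> int:
        return self.W.shape[1]

    def block_matrix(self, n_limbs: int = 4) -> np.ndarray:
        """Block-diagonal W for the whole-body activation vector,
        (n_limbs*31) x (n_limbs*k)."""
        k = self.n_synergies
        B = np.zeros((n_limbs * N_MUSCLES, n_limbs * k))
        for i in range(n_limbs):
            B[i * N_MUSCLES:(i + 1) * N_MUSCLES, i * k:(i + 1) * k] = self.W
        return B


def derive_synergy_pattern(limb_map: MuscleWrenchMap,
                           f: SynergyForceVector | np.ndarray) -> np.ndarray:
    """Minimum-effort activation reproducing endpoint force ``f``.

    Solves  min ||e||^2  s.t.  force rows of the map @ e = f,  0 <= e <= 1.
    Raises with the violated feasibility when no activation can produce
    ``f`` within bounds.
    """
    fv = f.force if isinstance(f, SynergyForceVector) else np.asarray(f, dtype=float)
    prob = QpProblem(H=2.0 * np.eye(N_MUSCLES),
                     A_eq=limb_map.force_rows, b_eq=fv,
                     lb=np.zeros(N_MUSCLES), ub=np.ones(N_MUSCLES))
    sol = solve_qp(prob)
    if sol.status != "optimal" or sol.eq_residual > 1e-6:
        raise ValueError(
            f"force vector {fv} infeasible for limb {limb_map.limb_id}: "
            f"best equality residual {sol.eq_residual:.2e} N")
    return sol.x


def build_synergy_basis(limb_map: MuscleWrenchMap,
                        force_vectors: list[SynergyForceVector]) -> SynergySet:
    """Derive the shared synergy matrix W from five force vectors.

    Patterns are derived once (in the preferred configuration's limb map)
    and reused bit-identically across limbs and stance configurations.
    Aborts naming the offending vector when one is infeasible.
    """
    if len(force_vectors) != N_SYNERGIES:
        raise ValueError(f"expected {N_SYNERGIES} synergy force vectors")
    cols = []
    for i, f in enumerate(force_vectors):
        try:
            cols.append(derive_synergy_pattern(limb_map, f))
        except ValueError as err:
            raise ValueError(f"synergy force vector {i + 1} infeasible: {err}") from err
    W = np.clip(np.column_stack(cols), 0.0, 1.0)
    return SynergySet(W=W, force_vectors=list(force_vectors),
                      provenance=f"derived from limb {limb_map.limb_id} wrench map")
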