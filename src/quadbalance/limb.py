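"""One limb's muscles and its static activation-to-endpoint-wrench map.

Under the quasi-static assumption the ground-reaction wrench a limb
produces is linear in muscle activation: joint torques are R F_AFL e
(moment-arm matrix times maximal forces scaled by force-length factors
times activation), and the endpoint wrench follows through the
Moore-Penrose pseudoinverse of the transposed geometric Jacobian,

    w = pinv(J^T) R F_AFL e.

Forelimbs are reduced to vertical struts: every wrench row except the
vertical force is zeroed.  Left limbs are mirrored from the right-limb
template by flipping the sign of the lateral (x) force row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinematics import N_DOF, KinematicChain, geometric_jacobian

log = logging.getLogger(__name__)

N_MUSCLES = 31

#: wrench row order used throughout the package
WRENCH_ROWS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")
ROW_FX, ROW_FY, ROW_FZ = 0, 1, 2
LATERAL_FORCE_ROW = ROW_FX
VERTICAL_FORCE_ROW = ROW_FZ

LIMB_IDS = ("LH", "RH", "LF", "RF")


@dataclass
class MuscleParams:
    """Static parameters of a single muscle.

    ``f_max`` is the maximal isometric force (N), ``fl_scale`` the
    force-length scaling factor at the static posture (unitless, in
    (0, 1]), ``mass`` the muscle mass in grams and ``moment_arms`` the
    7-vector of joint moment arms (m), one entry per kinematic DOF.
    """

    name: str
    f_max: float
    fl_scale: float
    mass: float
    moment_arms: np.ndarray

    def __post_init__(self) -> None:
        self.moment_arms = np.asarray(self.moment_arms, dtype=float)
        if not np.isfinite(self.f_max) or self.f_max <= 0:
            raise ValueError(f"{self.name}: f_max must be positive and finite")
        if not 0 < self.fl_scale <= 1:
            raise ValueError(f"{self.name}: fl_scale must be in (0, 1]")
        if not np.isfinite(self.mass) or self.mass <= 0:
            raise ValueError(f"{self.name}: mass must be positive and finite")
        if self.moment_arms.shape != (N_DOF,) or not np.all(np.isfinite(self.moment_arms)):
            raise ValueError(f"{self.name}: moment_arms must be a finite {N_DOF}-vector")


@dataclass
class LimbModel:
    """A limb: kinematic chain, muscle roster, Jacobian and placement."""

    limb_id: str
    kind: str  # "hindlimb" | "forelimb_strut"
    chain: KinematicChain
    muscles: list[MuscleParams]
    endpoint_position: np.ndarray
    mirrored: bool = False
    jacobian: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.limb_id not in LIMB_IDS:
            raise ValueError(f"limb_id must be one of {LIMB_IDS}")
        if self.kind not in ("hindlimb", "forelimb_strut"):
            raise ValueError("kind must be 'hindlimb' or 'forelimb_strut'")
        if len(self.muscles) != N_MUSCLES:
            raise ValueError(f"expected {N_MUSCLES} muscles, got {len(self.muscles)}")
        names = [m.name for m in self.muscles]
        if len(set(names)) != N_MUSCLES:
            raise ValueError("muscle names must be unique")
        self.endpoint_position = np.asarray(self.endpoint_position, dtype=float)
        if self.endpoint_position.shape != (3,):
            raise ValueError("endpoint_position must be a 3-vector")
        if self.jacobian is None:
            self.jacobian = geometric_jacobian(self.chain)
        else:
            self.jacobian = np.asarray(self.jacobian, dtype=float)
        if self.jacobian.shape != (6, N_DOF):
            raise ValueError(f"jacobian must be 6x{N_DOF}")

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    @property
    def moment_arm_matrix(self) -> np.ndarray:
        """R, the 7x31 moment-arm matrix (columns are muscles)."""
        return np.column_stack([m.moment_arms for m in self.muscles])

    @property
    def f_afl(self) -> np.ndarray:
        """Diagonal of F_AFL: maximal force times force-length scale (N)."""
        return np.array([m.f_max * m.fl_scale for m in self.muscles])

    @property
    def masses(self) -> np.ndarray:
        """Muscle masses in grams."""
        return np.array([m.mass for m in self.muscles])


@dataclass
class MuscleWrenchMap:
    """6x31 linear map from muscle activation to endpoint ground-reaction
    wrench (rows Fx, Fy, Fz, Mx, My, Mz; N and N·m per unit activation)."""

    matrix: np.ndarray
    limb_id: str
    kind: str = "hindlimb"
    muscle_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (6, N_MUSCLES):
            raise ValueError(f"wrench map must be 6x{N_MUSCLES}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("wrench map has non-finite entries")

    @property
    def force_rows(self) -> np.ndarray:
        """The 3x31 force part of the map."""
        return self.matrix[:3]

    @property
    def moment_rows(self) -> np.ndarray:
        """The 3x31 endpoint-moment part of the map."""
        return self.matrix[3:]


def compose_wrench_matrix(J: np.ndarray, R: np.ndarray, f_afl: np.ndarray) -> np.ndarray:
    """pinv(J^T) R diag(f_afl): endpoint wrench per unit activation.

    Works for any consistent dimensions (J is wrench-rows x DOF, R is
    DOF x muscles), so toy low-dimensional systems can be checked against
    hand computation.
    """
    return np.linalg.pinv(np.asarray(J, dtype=float).T) \
        @ np.asarray(R, dtype=float) @ np.diag(np.asarray(f_afl, dtype=float))


def build_wrench_map(limb: LimbModel) -> MuscleWrenchMap:
    """Compose pinv(J^T) R F_AFL into the limb's 6x31 wrench map.

    Forelimb struts keep only the vertical-force row; mirrored (left)
    limbs have the lateral-force row sign-flipped.  A rank-deficient J^T
    is logged as a warning and the pseudoinverse is still taken.
    """
    J = limb.jacobian
    R = limb.moment_arm_matrix
    if not (np.all(np.isfinite(J)) and np.all(np.isfinite(R))):
        raise ValueError("non-finite Jacobian or moment arms")
    rank = np.linalg.matrix_rank(J.T)
    if rank < 6:
        log.warning("limb %s: J^T rank %d < 6; pseudoinverse still taken",
                    limb.limb_id, rank)
        warnings.warn(f"limb {limb.limb_id}: rank-deficient Jacobian (rank {rank})",
                      stacklevel=2)
    matrix = compose_wrench_matrix(J, R, limb.f_afl)
    if limb.kind == "forelimb_strut":
        keep = matrix[VERTICAL_FORCE_ROW].copy()
        matrix = np.zeros_like(matrix)
        matrix[VERTICAL_FORCE_ROW] = keep
    if limb.mirrored:
        matrix[LATERAL_FORCE_ROW] *= -1.0
    return MuscleWrenchMap(matrix=matrix, limb_id=limb.limb_id, kind=limb.kind,
                           muscle_names=tuple(limb.muscle_names))


def endpoint_wrench(wmap: MuscleWrenchMap, activation: np.ndarray) -> np.ndarray:
    """Endpoint wrench of an activation vector; exactly linear.

    ``activation`` must be a 31-vector with entries in [0, 1].
    """
    a = np.asarray(activation, dtype=float)
    if a.shape != (N_MUSCLES,):
        raise ValueError(f"activation must have length {N_MUSCLES}")
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("activation entries must lie in [0, 1]")
    return wmap.matrix @ a
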