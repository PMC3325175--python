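"""Hindlimb kinematic chain: forward kinematics, segment angles, Jacobian.

The hindlimb is a three-segment (femur, shank, foot) chain with seven
rotational degrees of freedom: three at the hip (flexion, adduction,
internal rotation), two at the knee (flexion, varus) and two at the ankle
(flexion, inversion).  The world frame is right-handed with +x rightward,
+y anterior and +z up; segments hang along -z in the reference posture.

Segment orientation is summarised, as in gait analysis, by the sagittal-
and frontal-plane projection angles of each segment axis: the sagittal
angle is the rotation of the segment away from vertical within the y-z
plane, the frontal angle the rotation within the x-z plane.  Joint angles
are fitted to segment-angle targets by bounded local least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

DOF_NAMES = (
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "knee_varus",
    "ankle_flexion",
    "ankle_inversion",
)
N_DOF = 7

SEGMENT_NAMES = ("femur", "shank", "foot")

# joint angle excursion bounds (deg) used by the fitter
_Q_BOUNDS = (-150.0, 150.0)


@dataclass
class KinematicChain:
    """Three-segment, 7-DOF hindlimb chain.

    Parameters
    ----------
    segment_lengths : array-like of 3 floats
        Femur, shank and foot lengths in metres; all positive.
    joint_angles : array-like of 7 floats
        Joint angles ``q`` in degrees, ordered per :data:`DOF_NAMES`.
    """

    segment_lengths: np.ndarray
    joint_angles: np.ndarray = field(default_factory=lambda: np.zeros(N_DOF))

    def __post_init__(self) -> None:
        self.segment_lengths = np.asarray(self.segment_lengths, dtype=float)
        self.joint_angles = np.asarray(self.joint_angles, dtype=float)
        if self.segment_lengths.shape != (3,):
            raise ValueError("expected 3 segment lengths (femur, shank, foot)")
        if np.any(self.segment_lengths <= 0):
            raise ValueError("segment lengths must be positive")
        if self.joint_angles.shape != (N_DOF,):
            raise ValueError(f"expected {N_DOF} joint angles")
        if not np.all(np.isfinite(self.joint_angles)):
            raise ValueError("joint angles must be finite")


def _segment_rotations(q_deg: np.ndarray) -> list[Rotation]:
    """World-frame orientation of femur, shank and foot at joint angles q."""
    q = np.deg2rad(np.asarray(q_deg, dtype=float))
    # hip: flexion about x, adduction about y, internal rotation about z
    r_hip = Rotation.from_euler("xyz", [q[0], q[1], q[2]])
    # knee: flexion about x, varus about y, in the femur frame
    r_knee = r_hip * Rotation.from_euler("xy", [q[3], q[4]])
    # ankle: flexion about x, inversion about y, in the shank frame
    r_ankle = r_knee * Rotation.from_euler("xy", [q[5], q[6]])
    return [r_hip, r_knee, r_ankle]


def segment_directions(chain: KinematicChain, q_deg: np.ndarray | None = None) -> np.ndarray:
    """Unit axis (proximal-to-distal) of each segment in the world frame, 3x3."""
    q = chain.joint_angles if q_deg is None else np.asarray(q_deg, dtype=float)
    down = np.array([0.0, 0.0, -1.0])
    return np.array([r.apply(down) for r in _segment_rotations(q)])


def endpoint_position(chain: KinematicChain, q_deg: np.ndarray | None = None) -> np.ndarray:
    """Limb endpoint (toe) position relative to the hip, metres."""
    dirs = segment_directions(chain, q_deg)
    return dirs.T @ chain.segment_lengths


def segment_angles(chain: KinematicChain, q_deg: np.ndarray | None = None) -> np.ndarray:
    """Sagittal- and frontal-plane angles (deg) of femur, shank and foot.

    Returns a 6-vector ``[femur_sag, femur_fro, shank_sag, shank_fro,
    foot_sag, foot_fro]``.  Sagittal angle = atan2(v_y, -v_z); frontal
    angle = atan2(v_x, -v_z); both zero for a vertical segment.
    """
    dirs = segment_directions(chain, q_deg)
    out = np.empty(6)
    for i, v in enumerate(dirs):
        out[2 * i] = np.degrees(np.arctan2(v[1], -v[2]))
        out[2 * i + 1] = np.degrees(np.arctan2(v[0], -v[2]))
    return out


def geometric_jacobian(chain: KinematicChain, q_deg: np.ndarray | None = None,
                       step: float = 1e-6) -> np.ndarray:
    """6x7 geometric system Jacobian at q by central differences.

    Rows 0-2 are the endpoint linear velocity per unit joint rate, rows
    3-5 the angular velocity of the distal segment.  ``step`` is the
    central-difference step in radians.
    """
    q0 = chain.joint_angles if q_deg is None else np.asarray(q_deg, dtype=float)
    h_deg = np.degrees(step)
    J = np.zeros((6, N_DOF))
    r0 = _segment_rotations(q0)[2].as_matrix()
    for k in range(N_DOF):
        qp = q0.copy()
        qm = q0.copy()
        qp[k] += h_deg
        qm[k] -= h_deg
        J[:3, k] = (endpoint_position(chain, qp) - endpoint_position(chain, qm)) / (2 * step)
        # angular part: vee of the skew-symmetric dR R^T
        dR = (_segment_rotations(qp)[2].as_matrix()
              - _segment_rotations(qm)[2].as_matrix()) / (2 * step)
        S = dR @ r0.T
        J[3:, k] = [S[2, 1], S[0, 2], S[1, 0]]
    return J


@dataclass
class JointFitResult:
    """Outcome of fitting joint angles to segment-angle targets."""

    joint_angles: np.ndarray
    residual_deg: float
    converged: bool
    achieved_segment_angles: np.ndarray


def fit_joint_angles(chain: KinematicChain,
                     target_segment_angles: np.ndarray,
                     initial_guess: np.ndarray | None = None,
                     tol_deg: float = 1e-4) -> JointFitResult:
    """Fit q so chain segment angles match the six targets in least squares.

    Minimises the summed squared sagittal/frontal segment-angle error from
    a stated initial guess (default: mid-range zero posture).  The fit is
    flagged non-converged when the residual exceeds ``tol_deg`` degrees;
    the residual is always reported, never masked.
    """
    targets = np.asarray(target_segment_angles, dtype=float)
    if targets.shape != (6,):
        raise ValueError("expected 6 segment-angle targets (3 segments x 2 planes)")
    x0 = np.zeros(N_DOF) if initial_guess is None else np.asarray(initial_guess, dtype=float)

    def resid(q: np.ndarray) -> np.ndarray:
        return segment_angles(chain, q) - targets

    sol = least_squares(resid, x0, bounds=_Q_BOUNDS, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    achieved = segment_angles(chain, sol.x)
    residual = float(np.max(np.abs(achieved - targets)))
    return JointFitResult(
        joint_angles=sol.x,
        residual_deg=residual,
        converged=residual <= tol_deg,
        achieved_segment_angles=achieved,
    )
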