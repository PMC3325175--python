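"""Task-level equality targets per perturbation direction.

Perturbation direction theta is measured counterclockwise from +x viewed
from above (0 deg = rightward platform translation).  The CoM-wrench
target pins five components — horizontal force of 2.5 N along theta,
vertical force of 30 N, and a 0.75 N·m pitch-roll moment perpendicular to
theta — leaving the yaw moment free.  The CoP target is a 3.3 cm
displacement directed opposite the perturbation.

The perpendicular sense of the moment target is the moment a ground-level
restoring force below the CoM would produce, (0, 0, -h) x F, i.e. theta
rotated -90 deg; the sense is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

DEFAULT_HORIZONTAL_FORCE_N = 2.5
DEFAULT_VERTICAL_FORCE_N = 30.0
DEFAULT_PITCHROLL_MOMENT_NM = 0.75
DEFAULT_COP_DISPLACEMENT_CM = 3.3
N_DIRECTIONS = 12


@dataclass
class ComWrenchTarget:
    """Equality target on the net CoM wrench; yaw is never constrained."""

    direction_deg: float
    force: np.ndarray  # (Fx, Fy, Fz) N
    moment_horizontal: np.ndarray  # (Mx, My) N·m
    f_horizontal: float = DEFAULT_HORIZONTAL_FORCE_N
    f_vertical: float = DEFAULT_VERTICAL_FORCE_N
    m_pitchroll: float = DEFAULT_PITCHROLL_MOMENT_NM
    yaw_free: bool = True

    @property
    def equality_rhs(self) -> np.ndarray:
        """The 5 constrained wrench components (Fx, Fy, Fz, Mx, My)."""
        return np.concatenate([self.force, self.moment_horizontal])


@dataclass
class CopTarget:
    """Equality target on CoP displacement from the quiet-stance CoP."""

    direction_deg: float
    displacement_cm: np.ndarray  # (x, y) cm
    magnitude_cm: float = DEFAULT_COP_DISPLACEMENT_CM
    f_vertical: float = DEFAULT_VERTICAL_FORCE_N  # companion constraint

    @property
    def displacement_m(self) -> np.ndarray:
        return self.displacement_cm / 100.0


def build_com_target(theta_deg: float,
                     f_horizontal: float = DEFAULT_HORIZONTAL_FORCE_N,
                     f_vertical: float = DEFAULT_VERTICAL_FORCE_N,
                     m_pitchroll: float = DEFAULT_PITCHROLL_MOMENT_NM,
                     perpendicular_sense: int = -90) -> ComWrenchTarget:
    """CoM force/moment target for perturbation direction theta (deg)."""
    theta = float(theta_deg) % 360.0
    t = np.deg2rad(theta)
    force = np.array([f_horizontal * np.cos(t), f_horizontal * np.sin(t), f_vertical])
    p = np.deg2rad(theta + perpendicular_sense)
    moment = m_pitchroll * np.array([np.cos(p), np.sin(p)])
    return ComWrenchTarget(direction_deg=theta, force=force,
                           moment_horizontal=moment,
                           f_horizontal=f_horizontal, f_vertical=f_vertical,
                           m_pitchroll=m_pitchroll)


def build_cop_target(theta_deg: float,
                     magnitude_cm: float = DEFAULT_COP_DISPLACEMENT_CM,
                     f_vertical: float = DEFAULT_VERTICAL_FORCE_N) -> CopTarget:
    """CoP displacement target: ``magnitude_cm`` directed at theta+180 deg."""
    theta = float(theta_deg) % 360.0
    t = np.deg2rad(theta + 180.0)
    disp = magnitude_cm * np.array([np.cos(t), np.sin(t)])
    return CopTarget(direction_deg=theta, displacement_cm=disp,
                     magnitude_cm=magnitude_cm, f_vertical=f_vertical)


def perturbation_directions(n: int = N_DIRECTIONS) -> np.ndarray:
    """Evenly spaced perturbation directions in degrees, starting at 0."""
    return np.arange(n) * (360.0 / n)


@dataclass
class ConditionGrid:
    """Cartesian grid of perturbation directions x stance configurations."""

    directions_deg: np.ndarray
    stances: list  # list[StanceConfiguration]
    conditions: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.directions_deg = np.asarray(self.directions_deg, dtype=float)
        if not self.conditions:
            self.conditions = [(s, th) for s, th in
                               product(self.stances, self.directions_deg)]

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)


def enumerate_conditions(stances: list,
                         n_directions: int = N_DIRECTIONS) -> ConditionGrid:
    """All (stance, direction) conditions in deterministic order
    (stances as given, directions ascending from 0 deg)."""
    if len(stances) < 1:
        raise ValueError("at least one stance configuration required")
    return ConditionGrid(directions_deg=perturbation_directions(n_directions),
                         stances=list(stances))
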