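"""Four-limb assembly: the 6x124 activation-to-CoM-wrench map and the CoP.

The net CoM force is the sum of the four limb forces; the net CoM moment
is the sum of r_i x F_i with r_i the CoM-to-endpoint vector.  Endpoint
moments are discarded in the assembly (they contribute negligibly to the
net CoM moment).  Column order is fixed: LH 0-30, RH 31-61, LF 62-92,
RF 93-123.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .limb import LIMB_IDS, N_MUSCLES, LimbModel, MuscleWrenchMap, build_wrench_map

N_ACT = 4 * N_MUSCLES  # 124

STANCE_LABELS = ("longest", "preferred", "short", "shortest")


@dataclass
class StanceConfiguration:
    """Foot placement geometry for one experimental condition.

    ``stance_distance`` is the fore-hind foot separation, ``stance_width``
    the left-right separation (8 cm in the experimental paradigm) and
    ``com_height`` the CoM height above ground; all in centimetres at the
    interface, converted to metres internally.
    """

    stance_distance: float
    com_height: float
    stance_width: float = 8.0
    label: str = "preferred"
    animal_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.stance_distance <= 0 or self.stance_width <= 0 or self.com_height <= 0:
            raise ValueError("stance distance, width and CoM height must be positive")

    @property
    def endpoints_m(self) -> np.ndarray:
        """4x3 endpoint positions (m) in LH, RH, LF, RF order, z = 0."""
        w = self.stance_width / 200.0  # half-width, m
        d = self.stance_distance / 200.0  # half-distance, m
        return np.array([
            [-w, -d, 0.0],  # LH
            [+w, -d, 0.0],  # RH
            [-w, +d, 0.0],  # LF
            [+w, +d, 0.0],  # RF
        ])

    @property
    def com_height_m(self) -> float:
        return self.com_height / 100.0


@dataclass
class QuadrupedModel:
    """Four limbs, the CoM location and the assembled 6x124 wrench map."""

    limbs: list[LimbModel]
    limb_maps: list[MuscleWrenchMap]
    com_position: np.ndarray
    wrench_map: np.ndarray
    stance: StanceConfiguration | None = None
    muscle_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.com_position = np.asarray(self.com_position, dtype=float)
        self.wrench_map = np.asarray(self.wrench_map, dtype=float)
        if self.wrench_map.shape != (6, N_ACT):
            raise ValueError(f"wrench map must be 6x{N_ACT}")

    @property
    def endpoints(self) -> np.ndarray:
        """4x3 limb endpoint positions (m)."""
        return np.array([limb.endpoint_position for limb in self.limbs])

    @property
    def com_to_endpoints(self) -> np.ndarray:
        """4x3 CoM-to-endpoint vectors r_i (m)."""
        return self.endpoints - self.com_position

    def limb_slice(self, i: int) -> slice:
        """Activation-vector slice of limb i (LH=0, RH=1, LF=2, RF=3)."""
        return slice(i * N_MUSCLES, (i + 1) * N_MUSCLES)

    def limb_forces(self, activation: np.ndarray) -> np.ndarray:
        """4x3 ground-reaction forces of each limb for an activation vector."""
        a = np.asarray(activation, dtype=float)
        return np.array([
            self.limb_maps[i].force_rows @ a[self.limb_slice(i)] for i in range(4)
        ])

    def limb_endpoint_moments(self, activation: np.ndarray) -> np.ndarray:
        """4x3 endpoint moments of each limb (zero for forelimb struts)."""
        a = np.asarray(activation, dtype=float)
        return np.array([
            self.limb_maps[i].moment_rows @ a[self.limb_slice(i)] for i in range(4)
        ])

    def vertical_force_rows(self) -> np.ndarray:
        """4x124 matrix whose row i gives limb i's vertical force."""
        rows = np.zeros((4, N_ACT))
        for i in range(4):
            rows[i, self.limb_slice(i)] = self.limb_maps[i].matrix[2]
        return rows


def assemble_quadruped(limbs: list[LimbModel],
                       stance: StanceConfiguration) -> QuadrupedModel:
    """Place four limbs per the stance geometry and build the 6x124 map.

    The CoM sits horizontally at the centroid of the four endpoints at
    height h; column j of the map is [f_j ; r_i x f_j] with f_j the force
    part of muscle j's limb-map column.
    """
    if len(limbs) != 4:
        raise ValueError("exactly four limbs required")
    by_id = {limb.limb_id: limb for limb in limbs}
    if sorted(by_id) != sorted(LIMB_IDS):
        raise ValueError(f"limbs must carry unique ids {LIMB_IDS}")
    ordered = [by_id[i] for i in LIMB_IDS]

    endpoints = stance.endpoints_m
    for limb, pos in zip(ordered, endpoints):
        limb.endpoint_position = pos

    centroid = endpoints.mean(axis=0)
    com = np.array([centroid[0], centroid[1], stance.com_height_m])

    maps = [build_wrench_map(limb) for limb in ordered]
    W = np.zeros((6, N_ACT))
    for i, wmap in enumerate(maps):
        r = endpoints[i] - com
        F = wmap.force_rows  # 3x31
        cols = slice(i * N_MUSCLES, (i + 1) * N_MUSCLES)
        W[:3, cols] = F
        W[3:, cols] = np.cross(r, F.T).T
    names = tuple(f"{lid}_{name}" for lid, wmap in zip(LIMB_IDS, maps)
                  for name in wmap.muscle_names)
    return QuadrupedModel(limbs=ordered, limb_maps=maps, com_position=com,
                          wrench_map=W, stance=stance, muscle_names=names)


def net_com_wrench(model: QuadrupedModel, activation: np.ndarray) -> np.ndarray:
    """Net CoM force and moment (6-vector) of an activation vector."""
    a = np.asarray(activation, dtype=float)
    if a.shape != (N_ACT,):
        raise ValueError(f"activation must have length {N_ACT}")
    return model.wrench_map @ a


def compute_cop(vertical_forces: np.ndarray, endpoints_xy: np.ndarray) -> np.ndarray:
    """Centre of pressure from four vertical forces (N) and endpoint
    horizontal positions; the vertical-force-weighted centroid.

    Raises if the total vertical force is not positive.
    """
    fz = np.asarray(vertical_forces, dtype=float)
    p = np.asarray(endpoints_xy, dtype=float)
    if fz.shape != (4,) or p.shape != (4, 2):
        raise ValueError("expected 4 vertical forces and 4x2 endpoint positions")
    total = fz.sum()
    if total <= 0:
        raise ValueError("total vertical force must be positive; CoP undefined")
    return (p * fz[:, None]).sum(axis=0) / total


def cop_of_solution(model: QuadrupedModel, activation: np.ndarray) -> np.ndarray:
    """Nonlinear CoP recomputation from a solution's per-limb vertical forces."""
    forces = model.limb_forces(activation)
    return compute_cop(forces[:, 2], model.endpoints[:, :2])
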