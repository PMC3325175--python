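"""Seeded synthetic musculoskeletal models and pseudo-experimental data.

The real study rests on per-animal hindlimb parameters and recordings
that are not published, so every pipeline stage here runs on synthetic
stand-ins that reproduce the study's structure: 31 named hindlimb muscles
per limb, 7-DOF hindlimb kinematics, forelimbs as vertical struts,
an 8 cm stance width with per-animal stance distances and CoM heights,
12 perturbation directions at 30 deg spacing, and cosine-tuned
pseudo-EMG with diagonal force patterns for exercising the assessment
stage.  Everything is reproducible bit-for-bit from (config, seed).

Moment arms are anatomically signed (each muscle spans one or two
joints; antagonists carry opposite signs) but their magnitudes are
synthetic draws, not measurements of the cat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assessment import cosine_tuning
from .control import solve_mme
from .kinematics import N_DOF, KinematicChain
from .limb import N_MUSCLES, LimbModel, MuscleParams, MuscleWrenchMap, build_wrench_map
from .quadruped import QuadrupedModel, StanceConfiguration, assemble_quadruped
from .synergies import N_SYNERGIES, SynergyForceVector, derive_synergy_pattern
from .targets import ConditionGrid, build_com_target, enumerate_conditions

log = logging.getLogger(__name__)

#: the 31 hindlimb muscle abbreviations, alphabetical
MUSCLE_ROSTER = (
    "ADF", "ADL", "BFA", "BFP", "EDL", "FDL", "FHL", "GMAX", "GMED", "GMIN",
    "GRAC", "LG", "MG", "PB", "PEC", "PL", "PLAN", "PSOAS", "PT", "PYR",
    "QF", "RF", "SART", "SM", "SOL", "ST", "TA", "TP", "VI", "VL", "VM",
)

#: masses (g) printed for specific muscles; all others use DEFAULT_MASS_G
PRINTED_MASSES_G = {
    "LG": 12.4, "VL": 19.6, "PSOAS": 4.0, "SOL": 4.03, "VI": 4.39, "PT": 1.06,
}
DEFAULT_MASS_G = 4.0  # common low-midrange value for unlisted muscles

# DOF indices: 0 hip flexion, 1 hip adduction, 2 hip rotation,
# 3 knee flexion, 4 knee varus, 5 ankle flexion, 6 ankle inversion.
# Signs encode antagonist pairs (extensors negative flexion moment arms).
MUSCLE_ACTIONS: dict[str, tuple[tuple[int, float], ...]] = {
    "ADF": ((1, +1), (0, -1)),   # hip adductor / extensor
    "ADL": ((1, +1),),           # hip adductor
    "BFA": ((0, -1),),           # hip extensor
    "BFP": ((0, -1), (3, +1)),   # hip extensor / knee flexor
    "EDL": ((5, +1),),           # ankle dorsiflexor
    "FDL": ((5, -1),),           # ankle plantarflexor
    "FHL": ((5, -1),),           # ankle plantarflexor
    "GMAX": ((0, -1),),          # hip extensor
    "GMED": ((1, -1), (0, -1)),  # hip abductor / extensor
    "GMIN": ((1, -1),),          # hip abductor
    "GRAC": ((1, +1), (3, +1)),  # hip adductor / knee flexor
    "LG": ((5, -1), (3, +1)),    # ankle extensor / knee flexor
    "MG": ((5, -1), (3, +1)),    # ankle extensor / knee flexor
    "PB": ((6, -1),),            # ankle evertor
    "PEC": ((1, +1),),           # hip adductor
    "PL": ((6, -1), (5, -1)),    # ankle evertor / plantarflexor
    "PLAN": ((5, -1), (3, +1)),  # ankle extensor / knee flexor
    "PSOAS": ((0, +1),),         # hip flexor
    "PT": ((6, -1), (5, +1)),    # ankle evertor / dorsiflexor
    "PYR": ((2, +1), (1, -1)),   # hip external rotator / abductor
    "QF": ((2, -1), (0, -1)),    # hip rotator / extensor
    "RF": ((0, +1), (3, -1)),    # hip flexor / knee extensor
    "SART": ((0, +1), (3, -1)),  # hip flexor (modelled as such) / knee ext
    "SM": ((0, -1), (3, +1)),    # hip extensor / knee flexor
    "SOL": ((5, -1),),           # ankle plantarflexor
    "ST": ((0, -1), (3, +1)),    # hip extensor / knee flexor
    "TA": ((5, +1), (6, +1)),    # ankle dorsiflexor / invertor
    "TP": ((5, -1), (6, +1)),    # ankle plantarflexor / invertor
    "VI": ((3, -1),),            # knee extensor
    "VL": ((3, -1),),            # knee extensor
    "VM": ((3, -1),),            # knee extensor
}

# moment-arm magnitude ranges (m) by DOF group
_ARM_RANGES = {
    0: (0.010, 0.020), 1: (0.005, 0.012), 2: (0.003, 0.008),
    3: (0.006, 0.015), 4: (0.003, 0.008), 5: (0.004, 0.010), 6: (0.002, 0.006),
}
_FMAX_RANGE_N = (5.0, 120.0)  # log-uniform
_FL_RANGE = (0.7, 1.0)

#: per-animal geometry: stance distances (cm, decreasing), CoM height (cm)
ANIMAL_PRESETS = {
    "bi": {"stance_distances": (30.0, 27.0, 20.0, 13.0), "preferred": 27.0,
           "com_height": 12.6},
    "ru": {"stance_distances": (40.0, 29.0, 24.0, 18.0), "preferred": 29.0,
           "com_height": 15.2},
    "ni": {"stance_distances": (29.0, 24.0, 18.0), "preferred": 29.0,
           "com_height": 12.7},
}

_STANCE_LABELS_4 = ("longest", "preferred", "short", "shortest")
_STANCE_LABELS_3 = ("preferred", "short", "shortest")


@dataclass
class SyntheticStudyConfig:
    """Everything that determines a synthetic study; seed is mandatory."""

    seed: int
    animal_id: str = "bi"
    com_height_cm: float | None = None
    stance_distances_cm: tuple[float, ...] | None = None
    stance_width_cm: float = 8.0
    n_directions: int = 12
    segment_lengths_m: tuple[float, float, float] = (0.10, 0.11, 0.06)
    force_noise_sd_n: float = 0.5
    emg_noise_frac: float = 0.10
    muscle_roster: tuple[str, ...] = MUSCLE_ROSTER

    def __post_init__(self) -> None:
        preset = ANIMAL_PRESETS.get(self.animal_id)
        if self.com_height_cm is None:
            if preset is None:
                raise ValueError(f"unknown animal {self.animal_id!r}; give com_height_cm")
            self.com_height_cm = preset["com_height"]
        if self.stance_distances_cm is None:
            if preset is None:
                raise ValueError(
                    f"unknown animal {self.animal_id!r}; give stance_distances_cm")
            self.stance_distances_cm = preset["stance_distances"]
        if len(self.muscle_roster) != N_MUSCLES:
            raise ValueError(f"roster must have {N_MUSCLES} muscles")

    @property
    def stance_labels(self) -> tuple[str, ...]:
        n = len(self.stance_distances_cm)
        if n == 4:
            return _STANCE_LABELS_4
        if n == 3:
            return _STANCE_LABELS_3
        return tuple(f"stance{i}" for i in range(n))

    def stances(self) -> list[StanceConfiguration]:
        """Configurations sorted by decreasing stance distance."""
        dists = sorted(self.stance_distances_cm, reverse=True)
        return [StanceConfiguration(stance_distance=d, com_height=self.com_height_cm,
                                    stance_width=self.stance_width_cm,
                                    label=lab, animal_id=self.animal_id)
                for d, lab in zip(dists, self.stance_labels)]

    def preferred_stance(self) -> StanceConfiguration:
        preset = ANIMAL_PRESETS.get(self.animal_id)
        preferred = preset["preferred"] if preset else self.stance_distances_cm[0]
        for s in self.stances():
            if s.stance_distance == preferred:
                return s
        return self.stances()[0]


def _posture_for_stance(stance_distance_cm: float) -> np.ndarray:
    """Quiet-standing joint angles (deg); shorter stance = more crouched."""
    crouch = 1.0 + 0.3 * (27.0 - stance_distance_cm) / 27.0
    return np.array([35.0 * crouch, 3.0, 2.0, -65.0 * crouch, 2.0,
                     40.0 * crouch, 2.0])


def _draw_muscles(config: SyntheticStudyConfig, rng: np.random.Generator) -> list[MuscleParams]:
    muscles = []
    for name in config.muscle_roster:
        if name not in MUSCLE_ACTIONS:
            raise ValueError(f"unknown muscle name {name!r}")
        arms = np.zeros(N_DOF)
        for dof, sign in MUSCLE_ACTIONS[name]:
            lo, hi = _ARM_RANGES[dof]
            arms[dof] = sign * rng.uniform(lo, hi)
        f_max = float(np.exp(rng.uniform(np.log(_FMAX_RANGE_N[0]),
                                         np.log(_FMAX_RANGE_N[1]))))
        fl = float(rng.uniform(*_FL_RANGE))
        mass = PRINTED_MASSES_G.get(name, DEFAULT_MASS_G)
        muscles.append(MuscleParams(name=name, f_max=f_max, fl_scale=fl,
                                    mass=mass, moment_arms=arms))
    return muscles


def generate_hindlimb_model(config: SyntheticStudyConfig, seed: int | None = None,
                            limb_id: str = "RH",
                            stance_distance_cm: float | None = None) -> LimbModel:
    """A seeded 31-muscle hindlimb with anatomically signed moment arms.

    The same seed yields a bit-identical model.  Left limbs are mirrored
    (lateral-force sign flip in the wrench map).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d = stance_distance_cm
    if d is None:
        d = config.preferred_stance().stance_distance
    chain = KinematicChain(segment_lengths=np.array(config.segment_lengths_m),
                           joint_angles=_posture_for_stance(d))
    return LimbModel(limb_id=limb_id, kind="hindlimb", chain=chain,
                     muscles=_draw_muscles(config, rng),
                     endpoint_position=np.zeros(3),
                     mirrored=limb_id.startswith("L"))


def generate_forelimb_model(config: SyntheticStudyConfig, seed: int | None = None,
                            limb_id: str = "RF",
                            min_capacity_n: float = 40.0) -> LimbModel:
    """A forelimb strut: hindlimb template reduced to vertical force.

    f_max values are rescaled so quiet-stance weight support (about half
    the 30 N net vertical target per forelimb pair) is reachable at no
    more than 50% activation, i.e. upward capacity >= ``min_capacity_n``.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 17)
    chain = KinematicChain(segment_lengths=np.array(config.segment_lengths_m),
                           joint_angles=_posture_for_stance(27.0))
    muscles = _draw_muscles(config, rng)
    limb = LimbModel(limb_id=limb_id, kind="forelimb_strut", chain=chain,
                     muscles=muscles, endpoint_position=np.zeros(3),
                     mirrored=limb_id.startswith("L"))
    # a strut's muscles all push the ground: flip any template muscle whose
    # vertical-force gain came out negative (whole-column sign flip)
    wmap = build_wrench_map(limb)
    for j, m in enumerate(limb.muscles):
        if wmap.matrix[2, j] < 0:
            m.moment_arms = -m.moment_arms
    wmap = build_wrench_map(limb)
    capacity = float(wmap.matrix[2].sum())
    if capacity < min_capacity_n:
        scale = min_capacity_n / max(capacity, 1e-9)
        for m in limb.muscles:
            m.f_max *= scale
    return limb


def generate_quadruped_scenario(config: SyntheticStudyConfig,
                                stance: StanceConfiguration | None = None,
                                ) -> tuple[QuadrupedModel, ConditionGrid]:
    """Assemble the four-limb model at a stance plus its condition grid.

    Endpoints sit at (±width/2, ±distance/2); the CoM is at the endpoint
    centroid at the configured height; directions are evenly spaced.
    """
    if stance is None:
        stance = config.preferred_stance()
    limbs = [
        generate_hindlimb_model(config, limb_id="LH",
                                stance_distance_cm=stance.stance_distance),
        generate_hindlimb_model(config, limb_id="RH",
                                stance_distance_cm=stance.stance_distance),
        generate_forelimb_model(config, limb_id="LF"),
        generate_forelimb_model(config, limb_id="RF"),
    ]
    model = assemble_quadruped(limbs, stance)
    grid = enumerate_conditions([stance], n_directions=config.n_directions)
    return model, grid


def check_mme_feasible(model: QuadrupedModel, directions_deg=(0.0, 90.0, 180.0, 270.0)) -> bool:
    """True when MMe admits an optimal solution at the probe directions."""
    for th in directions_deg:
        if solve_mme(model, build_com_target(th)).status != "optimal":
            return False
    return True


def generate_feasible_scenario(config: SyntheticStudyConfig,
                               stance: StanceConfiguration | None = None,
                               max_attempts: int = 5,
                               ) -> tuple[QuadrupedModel, ConditionGrid]:
    """A scenario verified to admit feasible MMe solutions.

    Regenerates with a shifted seed when the feasibility probe fails,
    logging the attempt count.
    """
    from dataclasses import replace
    for attempt in range(max_attempts):
        cfg = config if attempt == 0 else replace(config,
                                                  seed=config.seed + 9973 * attempt)
        model, grid = generate_quadruped_scenario(cfg, stance)
        if check_mme_feasible(model):
            if attempt:
                log.info("feasible scenario found after %d regenerations", attempt)
            return model, grid
    raise RuntimeError(f"no feasible scenario within {max_attempts} attempts")


_SYNERGY_DIRECTIONS = np.array([
    [0.0, -0.45, 1.0],   # downward/backward diagonal
    [0.0, 0.45, 1.0],    # downward/forward diagonal
    [0.35, 0.0, 1.0],    # lateral
    [-0.35, 0.0, 1.0],   # medial
    [0.0, 0.0, 1.0],     # vertical
])


def generate_synergy_force_vectors(limb_map: MuscleWrenchMap, seed: int,
                                   max_fraction: float = 0.4,
                                   max_resamples: int = 20) -> list[SynergyForceVector]:
    """Five feasible endpoint-force targets for synergy derivation.

    Directions mimic the diagonal force-constraint-strategy geometry
    (downward/backward, downward/forward, lateral, medial, vertical);
    magnitudes are seeded draws below ``max_fraction`` of the limb's
    directional force capacity.  Infeasible draws are rejection-sampled
    with a logged count.
    """
    rng = np.random.default_rng(seed)
    F = limb_map.force_rows
    vectors: list[SynergyForceVector] = []
    for label, d in enumerate(_SYNERGY_DIRECTIONS, start=1):
        u = d / np.linalg.norm(d)
        capacity = float(np.clip(u @ F, 0.0, None).sum())  # max of u.(Fe) over box
        attempt = 0
        while True:
            frac = rng.uniform(0.15, max_fraction)
            f = SynergyForceVector(force=frac * capacity * u, label=label)
            try:
                derive_synergy_pattern(limb_map, f)
                break
            except ValueError:
                attempt += 1
                if attempt >= max_resamples:
                    raise
                log.info("synergy vector %d resampled (%d)", label, attempt)
        vectors.append(f)
    assert len(vectors) == N_SYNERGIES
    return vectors


@dataclass
class PseudoObservations:
    """Pseudo-experimental limb forces and EMG-like tuning values.

    ``forces`` has shape (n_stances, n_directions, 4, 3) N; ``emg`` shape
    (n_stances, n_directions, n_muscles), nonnegative.  The generating
    parameters and noiseless signals are retained for recovery tests.
    """

    stance_labels: tuple[str, ...]
    directions_deg: np.ndarray
    muscle_names: tuple[str, ...]
    forces: np.ndarray
    emg: np.ndarray
    forces_true: np.ndarray
    emg_true: np.ndarray
    ground_truth: dict = field(default_factory=dict)


def generate_pseudo_observations(config: SyntheticStudyConfig,
                                 seed: int | None = None,
                                 noise: float | None = None,
                                 stances: list[StanceConfiguration] | None = None,
                                 solve_forces: bool = True) -> PseudoObservations:
    """Pseudo-experimental forces and EMG across stances and directions.

    Forces are MMe solutions of the generating model plus Gaussian noise
    (``solve_forces=False`` substitutes a cheap parametric diagonal-force
    pattern).  EMG is rectified-cosine tuning (half-maximum widths of
    90-120 deg) whose peak amplitude scales linearly with stance while
    the peak direction stays fixed, plus nonnegative noise.  ``noise``
    overrides both configured noise levels as a common fraction.
    """
    if noise is not None and noise < 0:
        raise ValueError("noise scale must be nonnegative")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    stances = config.stances() if stances is None else stances
    dirs = np.arange(config.n_directions) * (360.0 / config.n_directions)
    n_s, n_d, n_m = len(stances), len(dirs), N_MUSCLES

    force_sd = config.force_noise_sd_n if noise is None else noise * 5.0
    emg_frac = config.emg_noise_frac if noise is None else noise

    peak_dirs = rng.uniform(0.0, 360.0, size=n_m)
    halfwidths = rng.uniform(90.0, 120.0, size=n_m)
    amplitudes = rng.uniform(0.2, 1.0, size=n_m)
    scale_slopes = rng.uniform(0.0, 0.15, size=n_m)  # per ordinal stance step

    forces_true = np.zeros((n_s, n_d, 4, 3))
    emg_true = np.zeros((n_s, n_d, n_m))
    for si, stance in enumerate(stances):
        if solve_forces:
            model, _ = generate_quadruped_scenario(config, stance)
            for di, th in enumerate(dirs):
                res = solve_mme(model, build_com_target(th))
                forces_true[si, di] = res.limb_forces
        else:
            for di, th in enumerate(dirs):
                t = np.deg2rad(th)
                hf = 1.5 * np.array([np.cos(t), np.sin(t)])
                for li, sx in enumerate([(-1, -1), (1, -1), (-1, 1), (1, 1)]):
                    forces_true[si, di, li] = [hf[0] * 0.5, hf[1] * 0.5,
                                               7.5 + 3.0 * np.cos(t - sx[0] * 0.5)]
        for mi in range(n_m):
            amp = amplitudes[mi] * (1.0 + scale_slopes[mi] * si)
            emg_true[si, :, mi] = cosine_tuning(dirs, peak_dirs[mi],
                                                halfwidths[mi], amp)

    forces = forces_true + rng.normal(0.0, force_sd, size=forces_true.shape)
    forces[..., 2] = np.clip(forces[..., 2], 0.0, None)  # VF >= 0
    emg_sd = emg_frac * np.maximum(emg_true.max(axis=(0, 1)), 1e-12)
    emg = np.clip(emg_true + rng.normal(0.0, emg_sd, size=emg_true.shape), 0.0, None)

    return PseudoObservations(
        stance_labels=tuple(s.label for s in stances),
        directions_deg=dirs, muscle_names=tuple(config.muscle_roster),
        forces=forces, emg=emg, forces_true=forces_true, emg_true=emg_true,
        ground_truth={"peak_dirs_deg": peak_dirs, "halfwidths_deg": halfwidths,
                      "amplitudes": amplitudes, "scale_slopes": scale_slopes},
    )
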