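"""Structured-text serialization: limb models and synergies as JSON,
optimization results as CSV rows.

Limb files record the muscle roster (name, f_max, fl_scale, mass,
moment_arms), segment lengths, joint angles, endpoint position and kind;
DOF order is 1-based in the file header note.  Result CSVs are keyed by
(animal, stance_cm, direction_deg, model).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .control import OptimizationResult
from .kinematics import DOF_NAMES, KinematicChain
from .limb import LimbModel, MuscleParams
from .quadruped import QuadrupedModel, StanceConfiguration
from .synergies import SynergyForceVector, SynergySet

_DOF_NOTE = ("DOF order (1-based): " +
             ", ".join(f"{i + 1}={n}" for i, n in enumerate(DOF_NAMES)))


def limb_to_dict(limb: LimbModel) -> dict:
    return {
        "_note": _DOF_NOTE,
        "limb_id": limb.limb_id,
        "kind": limb.kind,
        "mirrored": limb.mirrored,
        "segment_lengths_m": limb.chain.segment_lengths.tolist(),
        "joint_angles_deg": limb.chain.joint_angles.tolist(),
        "endpoint_position_m": limb.endpoint_position.tolist(),
        "muscles": [
            {"name": m.name, "f_max": m.f_max, "fl_scale": m.fl_scale,
             "mass": m.mass, "moment_arms": m.moment_arms.tolist()}
            for m in limb.muscles
        ],
    }


def limb_from_dict(d: dict) -> LimbModel:
    chain = KinematicChain(segment_lengths=np.array(d["segment_lengths_m"]),
                           joint_angles=np.array(d["joint_angles_deg"]))
    muscles = [MuscleParams(name=m["name"], f_max=m["f_max"],
                            fl_scale=m["fl_scale"], mass=m["mass"],
                            moment_arms=np.array(m["moment_arms"]))
               for m in d["muscles"]]
    return LimbModel(limb_id=d["limb_id"], kind=d["kind"], chain=chain,
                     muscles=muscles,
                     endpoint_position=np.array(d["endpoint_position_m"]),
                     mirrored=d["mirrored"])


def save_limb(limb: LimbModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(limb_to_dict(limb), indent=1))


def load_limb(path: str | Path) -> LimbModel:
    return limb_from_dict(json.loads(Path(path).read_text()))


def save_synergies(synergies: SynergySet, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "provenance": synergies.provenance,
        "force_vectors": [{"label": f.label, "force_n": f.force.tolist()}
                          for f in synergies.force_vectors],
        "W": synergies.W.tolist(),
    }, indent=1))


def load_synergies(path: str | Path) -> SynergySet:
    d = json.loads(Path(path).read_text())
    return SynergySet(W=np.array(d["W"]),
                      force_vectors=[SynergyForceVector(force=np.array(f["force_n"]),
                                                        label=f["label"])
                                     for f in d["force_vectors"]],
                      provenance=d.get("provenance", ""))


def results_to_frame(results: list[OptimizationResult],
                     model: QuadrupedModel | None = None,
                     include_activation: bool = False) -> pd.DataFrame:
    """One CSV-ready row per optimization result."""
    stance: StanceConfiguration | None = model.stance if model else None
    rows = []
    for r in results:
        row = {
            "animal": stance.animal_id if stance else "",
            "stance_cm": stance.stance_distance if stance else np.nan,
            "direction_deg": r.direction_deg,
            "model": r.model,
            "status": r.status,
            "effort": r.effort,
            "energy": r.energy,
            "solve_time_s": r.solve_time_s,
        }
        for k, name in enumerate(("Fx", "Fy", "Fz", "Mx", "My", "Mz")):
            row[f"com_{name}"] = r.achieved_wrench[k]
        for i, limb in enumerate(("LH", "RH", "LF", "RF")):
            for k, c in enumerate(("Fx", "Fy", "Fz")):
                row[f"{limb}_{c}"] = r.limb_forces[i, k]
        row["cop_x_cm"], row["cop_y_cm"] = r.cop_cm
        if include_activation:
            names = (model.muscle_names if model and model.muscle_names
                     else [f"act_{j}" for j in range(len(r.activation))])
            row.update(dict(zip(names, r.activation)))
        rows.append(row)
    return pd.DataFrame(rows)
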