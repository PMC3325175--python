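#!/usr/bin/env python
"""Solve the five optimal-control formulations across all conditions.

For every stance configuration and each of the 12 perturbation
directions, solves MMe (minimum muscle effort), MMm (mass-weighted
energy), MPe (CoP control), SMe and SMc (synergy-constrained variants),
and writes one row per solve — achieved CoM wrench, per-limb forces,
CoP, effort/energy, status and the 124 activation values — to
results/solutions.csv.

Usage:  python analysis/02_solve_programs.py [--seed 1] [--animal bi]
        [--models MMe MPe ...] [--stances 2]
"""

import argparse
from pathlib import Path

import pandas as pd

from quadbalance.control import solve_mme, solve_mmm, solve_mpe, solve_synergy
from quadbalance.io import results_to_frame
from quadbalance.limb import build_wrench_map
from quadbalance.synergies import build_synergy_basis
from quadbalance.synthetic import (
    SyntheticStudyConfig,
    generate_feasible_scenario,
    generate_hindlimb_model,
    generate_synergy_force_vectors,
)
from quadbalance.targets import build_com_target, build_cop_target, perturbation_directions

ALL_MODELS = ("MMe", "MMm", "MPe", "SMe", "SMc")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--animal", default="bi", choices=("bi", "ru", "ni"))
    ap.add_argument("--models", nargs="+", default=list(ALL_MODELS),
                    choices=ALL_MODELS)
    ap.add_argument("--stances", type=int, default=None,
                    help="limit to the first N stance configurations")
    ap.add_argument("--out", type=Path, default=Path("results/solutions.csv"))
    args = ap.parse_args()

    config = SyntheticStudyConfig(seed=args.seed, animal_id=args.animal)
    hindlimb_map = build_wrench_map(generate_hindlimb_model(config, limb_id="RH"))
    synergies = build_synergy_basis(
        hindlimb_map, generate_synergy_force_vectors(hindlimb_map, seed=config.seed + 1))

    stances = config.stances()[: args.stances]
    frames = []
    for stance in stances:
        model, _ = generate_feasible_scenario(config, stance)
        results = []
        for th in perturbation_directions(config.n_directions):
            com_t = build_com_target(th)
            if "MMe" in args.models:
                results.append(solve_mme(model, com_t))
            if "MMm" in args.models:
                results.append(solve_mmm(model, com_t))
            if "MPe" in args.models:
                results.append(solve_mpe(model, build_cop_target(th)))
            if "SMe" in args.models:
                results.append(solve_synergy(model, com_t, synergies, "muscle_effort"))
            if "SMc" in args.models:
                results.append(solve_synergy(model, com_t, synergies, "synergy_effort"))
        frames.append(results_to_frame(results, model, include_activation=True))
        n_opt = sum(r.status == "optimal" for r in results)
        print(f"stance {stance.label} ({stance.stance_distance:g} cm): "
              f"{n_opt}/{len(results)} optimal")

    df = pd.concat(frames, ignore_index=True)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"{len(df)} solves -> {args.out}")
    eff = df[df.status == "optimal"].groupby("model").effort.mean()
    print("mean effort by model:\n", eff.to_string())


if __name__ == "__main__":
    main()
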