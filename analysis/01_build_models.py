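#!/usr/bin/env python
"""Build the synthetic study's musculoskeletal models.

Generates the seeded hindlimb and forelimb-strut models, the per-animal
stance configurations, and the five-synergy basis derived from endpoint
force vectors in the preferred configuration, then writes them as JSON
under results/models/.

Usage:  python analysis/01_build_models.py [--seed 1] [--animal bi]
"""

import argparse
import json
from pathlib import Path

from quadbalance.io import save_limb, save_synergies
from quadbalance.limb import build_wrench_map
from quadbalance.synthetic import (
    SyntheticStudyConfig,
    generate_feasible_scenario,
    generate_hindlimb_model,
    generate_synergy_force_vectors,
)
from quadbalance.synergies import build_synergy_basis


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--animal", default="bi", choices=("bi", "ru", "ni"))
    ap.add_argument("--out", type=Path, default=Path("results/models"))
    args = ap.parse_args()

    config = SyntheticStudyConfig(seed=args.seed, animal_id=args.animal)
    args.out.mkdir(parents=True, exist_ok=True)

    model, grid = generate_feasible_scenario(config)
    for limb in model.limbs:
        save_limb(limb, args.out / f"{args.animal}_{limb.limb_id}.json")

    hindlimb_map = build_wrench_map(generate_hindlimb_model(config, limb_id="RH"))
    vectors = generate_synergy_force_vectors(hindlimb_map, seed=config.seed + 1)
    synergies = build_synergy_basis(hindlimb_map, vectors)
    save_synergies(synergies, args.out / f"{args.animal}_synergies.json")

    stances = [{"label": s.label, "stance_distance_cm": s.stance_distance,
                "stance_width_cm": s.stance_width, "com_height_cm": s.com_height}
               for s in config.stances()]
    (args.out / f"{args.animal}_stances.json").write_text(json.dumps(stances, indent=1))

    print(f"animal {args.animal}: 4 limb models, {len(stances)} stances, "
          f"{synergies.W.shape[1]} synergies -> {args.out}")
    print(f"wrench map {model.wrench_map.shape[0]}x{model.wrench_map.shape[1]}, "
          f"{len(grid)} conditions in the preferred stance alone")


if __name__ == "__main__":
    main()
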