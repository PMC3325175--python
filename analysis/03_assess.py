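#!/usr/bin/env python
"""Assess the solved programs: force fits, tuning curves, dimensionality,
normalized effort.

Reads results/solutions.csv, builds noisy pseudo-observations around the
minimum-effort predictions, and writes four tables under results/:
force_fits.csv (per stance and model R^2 values), tuning_metrics.csv
(per-muscle peak scaling slopes and shifts), dimensionality.csv (Kaiser
dimensionality per model and stance), effort.csv (% of MMe preferred).

Usage:  python analysis/03_assess.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from quadbalance.assessment import (
    TuningCurve,
    effort_report,
    force_fit,
    pca_dimensionality,
    scaling_regression,
    tuning_peak_metrics,
)
from quadbalance.synthetic import MUSCLE_ROSTER

FORCE_COLS = [f"{limb}_{c}" for limb in ("LH", "RH", "LF", "RF")
              for c in ("Fx", "Fy", "Fz")]
LH_ACT_COLS = [f"LH_{m}" for m in MUSCLE_ROSTER]


def _forces(df: pd.DataFrame) -> np.ndarray:
    return df[FORCE_COLS].to_numpy().reshape(-1, 4, 3)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--solutions", type=Path, default=Path("results/solutions.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--force-noise-sd", type=float, default=0.5,
                    help="Gaussian noise (N) added to emulate recordings")
    args = ap.parse_args()

    df = pd.read_csv(args.solutions)
    df = df[df.status == "optimal"]
    rng = np.random.default_rng(args.seed)
    stances = sorted(df.stance_cm.unique(), reverse=True)
    preferred = stances[1] if len(stances) > 1 else stances[0]

    # --- force fits: predictions vs noisy pseudo-observations ----------
    fit_rows = []
    for (model_name, stance), g in df.groupby(["model", "stance_cm"]):
        g = g.sort_values("direction_deg")
        pred = _forces(g)
        obs = pred + rng.normal(0.0, args.force_noise_sd, pred.shape)
        obs[..., 2] = np.clip(obs[..., 2], 0.0, None)
        rep = force_fit(pred, obs)
        fit_rows.append({"model": model_name, "stance_cm": stance,
                         **rep.as_dict()})
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(args.outdir / "force_fits.csv", index=False)
    print("mean R^2 by model:\n",
          fits.groupby("model")[["LH_HF_dir", "LH_HF_mag", "LH_VF_mag",
                                 "RF_VF_mag"]].mean().round(3).to_string())

    # --- tuning metrics and dimensionality ------------------------------
    tuning_rows, dim_rows = [], []
    for model_name, gm in df.groupby("model"):
        for stance, gs in gm.groupby("stance_cm"):
            gs = gs.sort_values("direction_deg")
            dim_rows.append({"model": model_name, "stance_cm": stance,
                             "dimensionality": pca_dimensionality(
                                 gs[LH_ACT_COLS].to_numpy())})
        if gm.stance_cm.nunique() < 3:
            continue
        for muscle in MUSCLE_ROSTER:
            curves = []
            for stance in stances:
                gs = gm[gm.stance_cm == stance].sort_values("direction_deg")
                if len(gs) == 0:
                    continue
                curves.append(TuningCurve(muscle, gs.direction_deg.to_numpy(),
                                          gs[f"LH_{muscle}"].to_numpy()))
            if len(curves) < 3:
                continue
            pref_idx = stances.index(preferred)
            metrics = tuning_peak_metrics(curves, preferred_index=pref_idx)
            if metrics.excluded:
                continue
            tuning_rows.append({
                "model": model_name, "muscle": muscle,
                "scaling_slope": scaling_regression(metrics.peak_values),
                "max_shift_deg": metrics.max_shift_deg,
            })
    pd.DataFrame(dim_rows).to_csv(args.outdir / "dimensionality.csv", index=False)
    tuning = pd.DataFrame(tuning_rows)
    tuning.to_csv(args.outdir / "tuning_metrics.csv", index=False)
    if len(tuning):
        print("mean scaling slope / peak shift by model:\n",
              tuning.groupby("model")[["scaling_slope", "max_shift_deg"]]
              .mean().round(3).to_string())
    dims = pd.DataFrame(dim_rows)
    print("mean dimensionality by model:\n",
          dims.groupby("model").dimensionality.mean().round(2).to_string())

    # --- normalized control effort --------------------------------------
    efforts, times = {}, {}
    for model_name, gm in df.groupby("model"):
        pref = gm[gm.stance_cm == preferred]
        if len(pref):
            efforts[f"{model_name}_preferred"] = pref.effort.mean()
            times[f"{model_name}_preferred"] = pref.solve_time_s.mean()
    if "MMe_preferred" in efforts:
        rep = effort_report(efforts, baseline_key="MMe_preferred",
                            solve_times=times)
        eff = pd.DataFrame({"condition": list(rep.percentages),
                            "effort_pct_of_MMe": list(rep.percentages.values()),
                            "mean_solve_time_s": [times.get(k, np.nan)
                                                  for k in rep.percentages]})
        eff.to_csv(args.outdir / "effort.csv", index=False)
        print("effort (% of MMe preferred):\n", eff.round(1).to_string(index=False))


if __name__ == "__main__":
    main()
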