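# quadbalance

Static optimal-control analysis of quadrupedal balance: how should a
standing quadruped distribute muscle activation across four limbs —
31 muscles each — so that the net force and moment at its center of
mass (CoM) restore balance after a support-surface translation?

The package is for computational neuromechanics work on the muscle- and
limb-redundancy problem in postural control: it builds the linear
muscle-to-wrench model, solves the competing task-level control
hypotheses as quadratic programs, and computes the metrics used to
compare them (limb-force fits, tuning-curve scaling and shifting, PCA
dimensionality, normalized control effort).

## Model

Each hindlimb maps activation `e ∈ [0,1]³¹` to an endpoint
ground-reaction wrench through static equilibrium,

    w = pinv(Jᵀ) · R · F_AFL · e

with `J` the 6×7 geometric Jacobian of the 7-DOF chain (hip 3, knee 2,
ankle 2), `R` the moment-arm matrix and `F_AFL` the diagonal of maximal
forces times force–length scalings. Forelimbs are vertical struts (all
rows but vertical force zeroed); left limbs mirror the right template.
Stacking four limbs about the CoM gives the 6×124 matrix whose columns
are `[fⱼ ; rᵢ × fⱼ]`, and the programs solved over it are

* **MMe** — min Σe² s.t. net CoM wrench = target (2.5 N horizontal along
  the perturbation, 30 N vertical, 0.75 N·m pitch-roll; yaw free),
  0 ≤ e ≤ 1, per-limb vertical force ≥ 0;
* **MMm** — same constraints, cost Σ mᵢeᵢ² (muscle-mass weighted);
* **MPe** — min Σe² s.t. center-of-pressure displacement = 3.3 cm
  opposite the perturbation;
* **SMe / SMc** — MMe's constraints with `e = W c` restricted to five
  muscle synergies per limb, minimizing ‖Wc‖² or ‖c‖²;
* **MMe0** — MMe with hindlimb endpoint moments pinned to zero.

Every solve is verified against the KKT optimality conditions by an
independent check, and equality constraints are satisfied to ~1e-12.
Because the original musculoskeletal parameters and cat recordings are
unpublished, a seeded synthetic study (`quadbalance.synthetic`) supplies
structurally faithful models — the 31 named muscles with anatomically
signed moment arms, printed muscle masses where known, the experimental
stance geometry — plus pseudo-observations for the assessment stage.
See `docs/methods.md` for the full model account.

## Worked example

```python
import quadbalance as qb

config = qb.SyntheticStudyConfig(seed=1)          # cat-bi geometry
model, grid = qb.generate_quadruped_scenario(config)
res = qb.solve_mme(model, qb.build_com_target(30.0))
print(res.status, res.achieved_wrench.round(6))
print(res.limb_forces.round(2))
```

prints

```
optimal [ 2.165064  1.25     30.        0.375    -0.649519  0.322472]
[[0.76 0.25 4.25]
 [1.4  1.   9.94]
 [0.   0.   6.04]
 [0.   0.   9.76]]
```

The achieved wrench meets the task exactly: 2.5 N of horizontal force at
30° (components 2.165, 1.25), 30 N of vertical support, a 0.75 N·m
pitch-roll moment perpendicular to the perturbation (components 0.375,
−0.6495), and a free yaw moment (0.322 N·m, unconstrained). The
limb-force rows (LH, RH, LF, RF) show the load shifted onto the right
hindlimb — 9.9 N vertical with a diagonal horizontal force — while the
struts contribute vertical force only: the "force constraint strategy"
emerging from effort minimization rather than being imposed.

The numbered drivers run the whole study and write tables under
`results/`:

```
python analysis/01_build_models.py   --seed 1    # limb/synergy JSON models
python analysis/02_solve_programs.py --seed 1    # 240 solves -> solutions.csv
python analysis/03_assess.py         --seed 1    # fits, tuning, dims, effort
```

On the seed-1 study the assessment prints, among others:

```
mean R^2 by model:        LH_HF_dir  LH_VF_mag
                   MMe        0.926      0.968
                   MPe       -0.032      0.969
mean dimensionality by model:  MMe 3.5   SMe 3.0   SMc 2.0
effort (% of MMe preferred):   SMe 178.1   SMc 254.5
```

i.e. CoP control reproduces vertical-force exchange but fails on
horizontal-force direction, synergy-constrained control reduces the
dimensionality of the predicted muscle patterns below muscle-level
control, and it costs roughly twice the minimum effort — the study's
qualitative fingerprint, recovered on synthetic parameters.

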