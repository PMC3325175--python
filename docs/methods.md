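# Methods

## Problem and model

During the automatic postural response to a horizontal support-surface
translation, a standing quadruped must restore its center of mass (CoM)
using forces generated by four limbs, each actuated by many muscles. The
response window is quasi-static: inertial and velocity-dependent terms
are negligible, the posture is essentially that of quiet standing, and
the ground-reaction forces can be attributed to muscle activation alone.
Under these assumptions the whole control problem becomes linear-algebraic,
and the redundancy — which muscles, and which limbs, produce the needed
net force and moment — can be resolved by constrained optimization.

### Limb model

Each hindlimb is a three-segment (femur, shank, foot) chain with seven
rotational degrees of freedom: hip flexion/adduction/internal-rotation,
knee flexion/varus, ankle flexion/inversion. A muscle with maximal
isometric force `f_max`, force–length scaling `fl` (evaluated once at
the static posture; no Hill dynamics) and moment-arm column `r` produces
joint torques `r · f_max · fl · e` at activation `e ∈ [0, 1]`. Static
equilibrium maps joint torques to an endpoint ground-reaction wrench
through the Moore–Penrose pseudoinverse of the transposed geometric
Jacobian:

    w = pinv(Jᵀ) R F_AFL e,          w ∈ R⁶ (Fx, Fy, Fz, Mx, My, Mz)

with `R` the 7×31 moment-arm matrix and `F_AFL = diag(f_max · fl)`. The
Jacobian is computed numerically from the chain's forward kinematics by
central differences (step 1e-6 rad); for a static map this is equivalent
to a closed-form Jacobian and avoids symbolic tooling. Rank deficiency
of `Jᵀ` is logged and the pseudoinverse still taken; on chains where a
degree of freedom is inert (zero Jacobian column and zero moment arms)
the pseudoinverse coincides exactly with locking that DOF.

Forelimbs are vertical struts: all wrench rows except vertical force are
zeroed. Left limbs are mirrored copies of the right template with the
lateral-force row sign-flipped.

### Coordinate and sign conventions

Right-handed frame, +x rightward, +y anterior, +z up. Perturbation
direction θ is measured counterclockwise from +x viewed from above, so
0° is a rightward translation. The wrench is the ground-reaction wrench
on the limb endpoint with vertical positive upward, so the constraint
VF ≥ 0 reads "limbs push, never pull". Segment angles are the sagittal
(y–z) and frontal (x–z) projection angles of each segment axis from
vertical; the exact segment-angle conventions are a declared choice of
this package, not recoverable from the source experiments.

### Quadruped assembly

Four limb maps are placed at endpoints (±width/2, ±distance/2, 0); the
CoM sits at the horizontal centroid of the endpoints at height `h`.
Column `j` of the 6×124 activation-to-CoM-wrench matrix is
`[f_j ; r_i × f_j]` with `f_j` the force part of muscle `j`'s limb
column and `r_i` the CoM-to-endpoint vector; endpoint moments are
discarded in the assembly, as their contribution to the net CoM moment
is negligible at this geometry. Column order is fixed: LH 1–31,
RH 32–62, LF 63–93, RF 94–124. The center of pressure (CoP) is the
vertical-force-weighted centroid of the endpoint positions.

## Task targets

For each of 12 evenly spaced directions the CoM-control models pin five
wrench components: horizontal force of 2.5 N along θ, vertical force of
30 N, and a 0.75 N·m pitch-roll moment perpendicular to θ; the yaw
moment is always free. The perpendicular sense of the moment target is
taken as the moment a ground-level restoring force below the CoM would
generate, `(0,0,−h) × F`, i.e. θ rotated −90°; only "perpendicular" is
specified by the source experiments, so the sense is configurable
(`perpendicular_sense=±90`).

The CoP-control model targets a 3.3 cm displacement directed opposite
the perturbation. "Net force unconstrained" is implemented with one
companion equality — net vertical force pinned to 30 N — which makes
the CoP equality exactly linear in activation
(`Σ (p_i − cop*) Fz_i = 0`); horizontal forces and CoM moments remain
free. The returned solution's CoP is always re-derived nonlinearly from
its four vertical forces as a check.

## The five programs

All are convex quadratic programs over activation `e ∈ [0,1]¹²⁴` with
per-limb vertical-force inequalities `VF_i ≥ 0`:

| model | variable space | task constraint | cost |
|-------|----------------|-----------------|------|
| MMe | 124 muscles | CoM wrench (5 eq) | Σ e² |
| MMm | 124 muscles | CoM wrench | Σ mᵢ eᵢ² (mass in g) |
| MPe | 124 muscles | CoP (2 eq) + VF total (1 eq) | Σ e² |
| SMe | 20 synergy coefficients | CoM wrench | ‖W c‖² |
| SMc | 20 synergy coefficients | CoM wrench | ‖c‖² |
| MMe0 | 124 muscles | CoM wrench + hindlimb endpoint moments = 0 | Σ e² |

Synergy control restricts each limb's activation to `e = W c`, `c ≥ 0`,
with the same 31×5 weighting matrix `W` in every limb and stance. `W` is
derived from the model itself: each column is the minimum-effort
activation reproducing one of five specified endpoint ground-reaction
force vectors, solved once in the preferred configuration and reused
bit-identically. The coefficient nonnegativity is taken relative to a
zero background with the full 30 N weight support inside the wrench
target — the background vertical force is part of the target, not a
separate offset variable. Activation bounds apply to `W c ≤ 1`
(`W c ≥ 0` holds automatically since both factors are nonnegative).
Stated open-interval activation bounds (0,1) are implemented as the
closed box [0,1]; complete unloading of a limb (VF = 0) is permitted.

### Numerical solution

No dedicated QP library is assumed: `quadbalance.qp` minimizes the
quadratic with SLSQP (analytic gradients, ftol 1e-14), then refines the
identified active set with a primal active-set iteration whose
equality-constrained subproblems are solved exactly through the KKT
linear system. Equality residuals therefore land at linear-solve
precision (≲1e-12 N), far inside the 1e-6 acceptance tolerance; bound
violations are held to 1e-8. Every returned solution is verified against
the first-order (KKT) conditions by an independent routine that
estimates multipliers with bounded least squares; solutions failing the
check at 1e-6 are not reported as optimal. Diagonal costs with positive
entries make MMe/MMm/SMc strictly convex and their solutions unique; SMe
adds a 1e-10 ridge on `c` because `WᵀW` can be rank-deficient.
Muscle columns that are identically zero (after the strut reduction)
stay in the variable vector for index stability; their optimal
activation is zero by cost.

Infeasible problems (constraints incompatible at the search's best
point) are reported as such, never masked. `relax_and_resolve` converts
the per-limb VF inequalities to a smooth one-sided quadratic penalty
(default weight 1e3) while keeping the equalities hard; results are
flagged `relaxed` and excluded from assessment aggregates, and the
penalty weight → ∞ recovers the hard solution on feasible problems. The
zero-endpoint-moment variant genuinely fails to converge at a minority
of directions on synthetic models (the extra six equalities can be
incompatible with the bounds), which is reported, not repaired.

## Joint-angle fitting

Model postures are fitted to segment-angle targets (sagittal and frontal
angles of femur, shank and foot) by bounded local least squares
(±150° per joint, mid-range zero initial posture unless a guess is
given), deterministic and seed-free. The fit is flagged converged only
when the residual is at or below 1e-4 degrees, the precision reported
for the original parameterization; unreachable targets yield a flagged
result with its residual.

## Synthetic study

The original musculoskeletal parameters and recordings are unpublished,
so the generator builds structural stand-ins, fully determined by a
seed:

* **Roster** — the 31 named hindlimb muscles, with anatomically signed
  moment arms: each muscle spans one or two joints, antagonists carry
  opposite signs, magnitudes drawn from per-joint ranges (hip 1–2 cm,
  knee 0.6–1.5 cm, ankle 0.4–1 cm, non-flexion DOFs smaller). The
  sparsity/sign structure is anatomical; the magnitudes are synthetic,
  not measurements of the cat.
* **Masses** — printed values where known (LG 12.4, VL 19.6, PSOAS 4.0,
  SOL 4.03, VI 4.39, PT 1.06 g); all others a common low-midrange
  default of 4.0 g.
* **Strengths** — `f_max` log-uniform in 5–120 N (typical feline
  hindlimb scale), `fl` uniform in 0.7–1.0.
* **Geometry** — stance width 8 cm; per-animal stance distances
  (bi 30/27/20/13, ru 40/29/24/18, ni 29/24/18 cm) and CoM heights
  (bi 12.6, ru 15.2, ni 12.7 cm); CoM at the endpoint centroid; quiet
  posture more crouched at shorter stances.
* **Forelimb struts** — the hindlimb template reduced to its vertical
  row; template muscles whose vertical gain is negative are sign-flipped
  (a strut's muscles all push the ground) and `f_max` rescaled so ≥40 N
  of upward force is available per strut, i.e. quiet-stance weight
  support at ≤50% activation. Without the sign-flip the synergy
  constraint can strangle strut vertical capacity and make the 30 N
  weight-support target infeasible.
* **Synergy force vectors** — five directions mimicking the diagonal
  force pattern seen experimentally (downward/backward,
  downward/forward, lateral, medial, vertical), magnitudes seeded draws
  at 15–40% of the limb's directional capacity, rejection-sampled
  against feasibility.
* **Pseudo-observations** — limb forces are MMe solutions plus Gaussian
  noise (default SD 0.5 N); EMG is rectified-cosine direction tuning
  with seeded peaks, half-maximum widths of 90–120°, amplitudes scaling
  linearly with stance while peak direction stays fixed, plus
  nonnegative noise (default 10% of peak). Generating parameters are
  retained for recovery tests.

Generated scenarios are probed for MMe feasibility at four directions
and regenerated from a shifted seed if the probe fails (logged; not
observed in practice at the default conditions).

What passing tests on this synthetic study do **not** show: anatomical
fidelity of moment arms or strengths, fit quality against real
recordings (the original R² tables depend on unpublished data), or any
dynamic/feedback property of balance — the model is static by design.
What they do show: the pipeline's structural claims (map dimensions,
condition counts), exact constraint satisfaction of all five programs,
the optimality of every reported solution, and the ordinal/qualitative
phenomena that are consequences of the formulation itself (effort
nesting between muscle and synergy control, reduced dimensionality
under synergy control, CoP control producing different horizontal-force
structure than CoM control).

## Assessment metrics

* **Force fits** — R² = 1 − SSres/SStot per component across the 12
  directions, computed separately for left-hindlimb horizontal-force
  direction and magnitude, left-hindlimb vertical force and
  right-forelimb vertical force (vertical magnitudes are several times
  horizontal ones). Direction residuals are wrapped to (−180°, 180°]
  before squaring; whether the original analysis wrapped is unknown, so
  the circular handling is explicit and configurable. Zero-variance
  observed series return NaN.
* **Tuning peaks** — peaks are tracked within ±90° of the
  preferred-configuration dominant peak (so multimodal curves follow
  the dominant lobe rather than the global maximum), values expressed
  relative to preferred; shift is the maximum circular change in peak
  direction. Scaling is the OLS slope of peak value on ordinal stance
  code 1 (longest) … n (shortest) — increasing activation at shorter
  stance gives a positive slope. Noisy peak directions are recovered by
  least-squares fitting of the rectified-cosine template (argmax-bin
  initialisation), which keeps 90% of recovery errors below 15° at 10%
  noise on a 30°-spaced grid.
* **Dimensionality** — the Kaiser criterion: eigenvalues ≥ 1.0 of the
  correlation matrix of the 12×31 activation matrix, zero-variance
  columns dropped first.
* **Effort** — Σe² normalized to 100% of MMe in the preferred
  configuration; solve times are logged but never used as an acceptance
  quantity (they are hardware-dependent).
* ANOVA/t-test/Bonferroni machinery from the original analysis is not
  reimplemented; the pipeline emits the per-condition tables such tests
  would consume.

## Problem sizes and defaults

The analysis drivers and acceptance script run one animal (bi geometry,
4 stances × 12 directions × 5 models = 240 solves, about two minutes on
one CPU); the acceptance script runs the preferred stance only (36
solves). These sizes are the package's chosen study scale — each solve
is independent, so larger sweeps parallelize trivially.

## Known limitations

* Static only: no muscle activation/contraction dynamics, no tendon
  compliance, no feedback simulation of the CoM trajectory.
* The forelimb strut discards real forelimb horizontal forces.
* Synthetic moment arms reproduce sign structure, not anatomy; absolute
  effort values and activation magnitudes are therefore not comparable
  to the original study, only their ordering and constraint behaviour.
* The SLSQP-plus-active-set solver is dense and suited to hundreds of
  variables, not thousands.
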