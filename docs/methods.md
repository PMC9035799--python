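# Methods

This note documents the model, its assumptions, the synthetic study
conditions, the numerical choices, and the known limitations of `kneesim`.

## Scope and modeling philosophy

`kneesim` isolates the *passive* mechanics of a cruciate-retaining TKA knee:
a calibrated nonlinear ligament apparatus, a parametric implant
articulation, and a quasi-static force balance driven by prescribed knee
flexion and intersegmental loads.  Muscle recruitment, full-body inverse
dynamics, marker-driven kinematics, subject-specific bone and implant
geometry and the patellofemoral articulation are deliberately outside the
model.  Everything the solver computes can be re-derived by summing forces
by hand, which is the intended trade: transparency and testability at desk
scale over in-vivo fidelity.

## Coordinate conventions

Right knee.  Both body frames use x anterior, y superior, z lateral (medial
is negative z); the tibia is the ground body with its origin at the knee
center on the joint line.  The femoral pose is a fixed Z-X-Y intrinsic Euler
sequence — flexion about z, then varus/valgus about x (varus positive,
closing the medial gap), then internal/external rotation about y (tibial
internal positive) — plus a translation (anterior, superior, medial
positive).  The decomposition is exactly invertible in the physiologic
range; the gimbal singularity sits at ±90° varus/valgus.

## Ligament apparatus

Twenty-one bundles in seven anatomical groups (2 ALL, 2 LCL, 5 MCL-group
including two deep-MCL bundles, 2 PCL, 4 posterior-capsule, 3 MPFL,
3 LPFL).  Each is a tension-only spring along the straight line between
attachments (no wrapping); the anterior cruciate is absent, as in the
cruciate-retaining implant.  The force-strain law is piecewise
quadratic/linear with a toe region up to twice the linear-limit strain ε₁;
it is continuous and once-differentiable at both breakpoints, which matters
for the Newton solver.

* **ε₁ = 0.03 for every bundle.**  The linear-limit strain of this law is
  not separately identifiable from the data we model against; 0.03 is the
  conventional value for this piecewise-quadratic ligament law.  It is a
  per-bundle config field, not a hard-coded constant.
* **Reference strains and stiffnesses** are the packaged 18-class table
  (`data/ligament_parameters.yaml`); the posterior capsule class expands
  into four bundles sharing one parameter row.  Negative reference strains
  (aPCL −0.10, pPCL −0.05) mean those bundles are slack at extension and
  engage only in flexion.
* **Attachment geometry is synthetic.**  Subject CT geometry is not
  available at desk scale, so the packaged attachment set
  (`data/attachments.yaml`) is a documented generic right knee: collateral
  origins on the epicondyles at ±45 mm from the midline near the flexion
  axis, insertions 28–52 mm distal, cruciates and capsule
  posterior-central, patellofemoral insertions in a patellar surrogate
  frame held rigid with the tibia.  Extension lengths fall in the
  physiologic 25–60 mm range.  All coordinates are overridable.  Because
  some synthetic bundles are short (deep MCL ≈ 25 mm), a given coronal
  rotation produces larger strain offsets than in a CT-derived model —
  laxity and pre-tension *directions* are faithful, their magnitudes are
  scaled up.
* **Calibration** sets every slack length from the bundle length at a seated
  extension pose so the bundle carries exactly its reference strain there:
  l₀ = l_ref/(1 + ε_r).  (The alternative convention l₀ = l_ref(1 + ε_r) is
  not self-consistent with ε = (l − l₀)/l₀: substituting the reference
  length would return −ε_r/(1+ε_r) rather than ε_r.)
* **Activation**: a bundle is "tight" when its tension exceeds 1 N — a
  reporting threshold, configurable, with no effect on mechanics.

The six patellofemoral bundles are registered, calibrated and reported but
excluded from the tibiofemoral balance; quadriceps action is implicit in the
external load profile.

## Implant articulation and contact

Each femoral condyle is a sphere of radius R_f = 24 mm centered on the
flexion axis at ±22 mm from the midline; the tibial insert carries two
dished pockets of radius R_i = 26 mm at the mirrored positions.  Contact is
classical internal sphere-in-socket: free while the condyle center stays
within the radial clearance R_i − R_f of the pocket center, elastic overlap
`depth = |offset| − clearance` beyond it (condyle center in the dished lower
half), force K_c·depth along the offset direction back toward concentricity.

This is a deliberate design choice over the superficially simpler inverted
law (`depth = clearance − |offset|`, force pointing away from the pocket
center), which we implemented first and rejected: that law is tangentially
destabilizing (the force tilts away from center as the condyle shifts),
degenerate at concentricity, and non-monotone in descent, so a model with
one slack collateral side could lower its energy by sinking and tilting into
spurious equilibria several degrees of varus/valgus away.  The restoring
law eliminates all three defects while leaving every closed-form property
used for verification (two-point statics, mirror symmetry, TCF = MCF + LCF,
continuity in pose) unchanged.

K_c = 5000 N/mm (linear exponent) keeps overlaps below ~0.5 mm at 3 body
weights while remaining well-conditioned for the Newton solve.  Friction is
zero.  Contact pressure distributions and insert stress are out of scope.

## Alignment variants and laxity construction

Component varus/valgus rotates the *implant geometry* about the
anterior-posterior axis through the component origin (midpoint of the
compartment centers); ligament footprints are bone-fixed and do not move.
A varus tibial cut tilts the pockets medial-side-down in the tibial frame; a
varus femoral cut resects more medial distal bone, i.e. rotates the condyle
geometry the opposite way in the femoral frame — either way the seated knee
ends up in bony varus.

The balancing pose for each variant is a *seated* extension pose: coronal
angle fixed, translations solved from a ligaments-disabled contact balance
under a nominal 100 N axial preload (the marker-based reference pose of a
motion-capture pipeline needs a self-contained substitute; the preload makes
the pose well-defined).  For the tilted poses on neutral components (models
D and G) the seating is one-sided — the compressed compartment stays
reduced, exactly the pivot depicted in a gap-balancing diagram.  All 21
bundles are balanced at that single pose.  Returning the joint to neutral
then leaves the gap-opened side slack (medial in D, lateral in G) and the
opposite side pre-tensioned; the 2° presets are the clinical question, but
the underlying operations accept any angle up to ±10°.

## Synthetic gait trial

The generator emulates the structure of an instrumented-implant overground
gait trial, producing knee-level intersegmental loads directly (sums of
Gaussian bumps, all shape parameters exposed):

| parameter | default | rationale |
|---|---|---|
| body mass | 66.7 kg | the modeled subject class |
| cycle duration / samples | 1.1 s / 101 | typical gait cycle |
| stance fraction | 0.60 | standard gait convention |
| flexion | 0–65°, stance wave ~18° | walking range; normalized to exactly [0, peak] |
| axial force | two equal stance peaks at 2.5 BW | instrumented-knee magnitude |
| swing axial floor | 0.05 BW | the joint is never fully unloaded; also keeps the equilibrium problem single-basin |
| adduction moment | 12.0 N·m per kN axial | tuned **once** so model A's cycle-average medial share ≈ 65% (measured 64.9%), then frozen; implied peak ≈ 19.6 N·m ≈ 1.8% BW·Ht, physiologic |
| AP force / ML force / axial moment | ≤ 0.10 / 0.04 BW, ≤ 3 N·m | small smooth profiles |
| noise | off by default; multiplicative Gaussian, seeded | determinism contract |

What the generator does **not** emulate: ground reaction forces and marker
trajectories (the loads are already knee-level), inter-subject variability,
step-to-step variability, and any feedback of joint state on load (the same
profile drives every variant).  Consequently, passing tests show the passive
model responds correctly to a *fixed, plausible* loading — not that it
predicts any individual subject's loads.

## Equilibrium solver

Flexion is prescribed; the five secondary DOFs are solved per step.  The
residual stacks three forces [N] and the varus/valgus and axial moments
[N·m] about the knee center (the flexion moment is the reaction of the
prescribed DOF); moments are scaled by a 50 mm lever to commensurate units
inside the norm.  Numerical scheme, in order:

1. trust-region least-squares descent with a fixed physical DOF scaling
   (the superior-inferior direction rides on the contact stiffness and is
   ~100× stiffer than the in-plane DOFs — without this scaling the
   iteration can escape the local basin);
2. MINPACK damped-Newton/dogleg (`hybr`) and Levenberg–Marquardt retries;
3. a fixed, deterministic fan of 12 perturbed restarts.

Convergence is declared per component (|F| < 0.1 N, |M| < 0.01 N·m) and
re-checked from the returned pose, independent of optimizer exit status.
The cycle is solved sequentially with warm starts; the initial seed is the
variant's own calibration pose (its neutral seated pose for the laxity
variants), which selects the physiologic equilibrium branch — the passive
joint also admits self-stressed "jammed" equilibria several degrees away,
which are genuine roots but not the operating point.  Finite-difference
Jacobians throughout; no randomness anywhere in the solve.

Degenerate inputs: empty load profiles, non-increasing time stamps, NaN
poses and uncalibrated models are rejected with explicit errors; a
non-converged step aborts the run with its index unless the caller opts
out.

## Validation metrics

RMSE and Pearson's r against measured compartment-force series (resampled
by linear interpolation onto the simulated percent-cycle grid), peaks and
percent changes against the neutral model, activation fraction and
crossing points per collateral group, kinematic extremes per DOF, and the
cycle-average medial share (sum of MCF over sum of TCF).  Peaks are taken
on the raw solved grid without smoothing — reproducibility over cosmetics.

## Problem sizes

The shipped study runs 7 variants × 101 equilibrium steps (each a 5-DOF
root solve with ~20 finite-difference residual evaluations); a full
pipeline takes ~15 s on one CPU, and the whole test suite, which runs the
pipeline plus a mirrored-model cycle and several hundred unit checks,
about half a minute.

## Known limitations

* No muscles: the same external loads drive every variant, so alignment
  effects that in vivo arise through muscle co-contraction and altered
  inverse-dynamics moments (e.g. the extra contact force a varus limb
  accrues from a longer adduction moment arm) are absent.  In this passive
  model the balanced-at-their-own-alignment variants (B, C, E) land within
  ±0.25% of neutral in peak TCF, and lateral laxity (G) *lowers* peak TCF
  (the slack lateral ligaments simply stop pulling) — in a muscle-driven
  model it raises it.  Directional laxity effects (D unloads the MCL and
  the joint; F loads hardest; F > E) do emerge from the passive mechanics.
* Straight-line bundles, no wrapping; posterior capsule wrapping around the
  condyles is ignored.
* The two-sphere articulation has no posterior lip or sagittal dishing
  beyond its radial clearance; deep flexion beyond ~65° is outside the
  model's validity.
* The patellofemoral joint is not solved; its six bundles are bookkeeping.
* Synthetic attachment geometry scales strain offsets up relative to a
  CT-derived knee (short deep-MCL bundles); tensions are comparable across
  variants, not calibrated to in-vivo magnitudes.
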