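# Methods

This note documents the models behind `exoassist`, their assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic gait generator

The generator replaces an instrumented-treadmill dataset. A population is
drawn from normal anthropometrics (mass 68.5 ± 11.33 kg, height
1.71 ± 0.07 m, male fraction 13/22); segment dimensions are standard
fractions of stature (thigh 0.245, calf 0.246, foot 0.152, torso 0.288,
pelvis width 0.191) with 3% relative jitter. Each gait cycle is
time-normalized to 101 samples (0–100% in 1% steps).

Angle and moment curves are piecewise cubic Hermite interpolants with zero
slope at every landmark knot, so each landmark is attained *exactly* and the
curves are C¹. Landmark values interpolate linearly in speed between
calibration anchors:

| landmark                    | 0.5 m/s | 1.8 m/s |
|-----------------------------|---------|---------|
| max dorsiflexion (at 45%)   | 25°     | 15°     |
| max plantarflexion angle    | 0°      | 15°     |
| plantarflexion-peak timing  | 70%     | 60%     |
| peak net moment             | 1.1 Nm/kg | 1.7 Nm/kg |
| peak-moment timing          | 50%     | 45%     |

An early-stance dorsiflexor dip (−0.15 to −0.20 Nm/kg at 4%) and a
zero-moment swing phase complete the moment curve. Stride length follows
1.25·√v m (giving cadence 85–125 steps/min over the speed range), and
maximum heel clearance 0.02 + 0.01·v m; both are named movement features,
not modeled mechanics. Noise is multiplicative on landmark amplitudes
(default SD 0.05) and additive on landmark timings (SD 1% of cycle), with a
per-subject random effect of the same scale so a subject's cycles are
correlated. With `noise_sd=0` the generator is an exact calibration oracle.

What the generator does *not* emulate: ground reaction forces, marker
trajectories, bilateral asymmetry, within-stride variability beyond the
landmark perturbations, and fatigue or age effects. Tests passing on these
synthetic cycles therefore demonstrate correctness of the pipeline's
mechanics and statistics, not validity on experimental gait data.

## Musculotendon model

Three lumped actuators span the ankle: soleus (Fmax 3549 N) and combined
gastrocnemius (2241 N) as plantarflexors, tibialis anterior (905 N) as
dorsiflexor — published musculoskeletal-model scale values. Forces follow
the rigid-tendon multiplicative Hill form F = a·Fmax·f_L(l)·f_V(v) with a
Gaussian force–length curve (width 0.45) and a Hill hyperbola
force–velocity relation clipped at 1.4 eccentric. Activation is bounded to
[0.02, 1]; the floor models resting tone. Moment arms are low-order
polynomials in the ankle angle (soleus/gastrocnemius ≈ 0.048 m, tibialis
≈ 0.037 m at neutral, mild angle dependence, magnitude capped at 0.08 m).

Because the tendon is rigid, `optimal_fiber_length` is an *effective*
musculotendon length scale (0.22–0.30 m) chosen so normalized length stays
within ≈ [0.85, 1.15] over the physiological angle range; anatomical fiber
lengths (~5 cm) would produce absurd excursions without tendon compliance.
Fiber kinematics follow d(length)/dθ = −r_axis with r_axis the moment arm
signed about the dorsiflexion-positive axis, so plantarflexors lengthen as
the ankle dorsiflexes.

The gastrocnemius is biarticular; its knee-flexion duty cannot be removed
by ankle assistance. This is represented by an optional *knee-demand
floor*: a minimum gastrocnemius activation during stance (0–63% of cycle).
It is off by default (floor = the global 0.02); enabling it (e.g. 0.3)
reproduces the characteristic muscle-level pattern in which optimal
assistance spares soleus and tibialis anterior but not gastrocnemius.

## Static optimization and assistance conditions

At each phase sample the net moment demand is distributed by minimizing
J = Σ aᵢ² + Σ (τⱼ/wⱼ)² subject to the linear moment balance, activations in
[0.02, 1] and actuator boxes. A reserve actuator (w = 1, ±25 Nm) covers
demand the muscles cannot meet; the ideal assistive actuator (w = 10⁶,
unbounded) is present only under the OA condition. Since muscle force is
linear in activation under the rigid-tendon law, the problem is a separable
box-constrained QP with one equality; it is solved exactly by parametric
KKT analysis — each variable is a clipped linear function of the Lagrange
multiplier, the balance is piecewise linear and non-decreasing in it, and
the root is found by sorting the clip breakpoints and solving the
containing segment. This yields machine-precision balance residuals
(≪ 1e-6 Nm tolerance), deterministic results, and ~1 ms per cycle.

Conditions:

- **No-exo** — bare leg.
- **NA** — device worn, unpowered. The sole (0.5 kg at 0.10 m anterior of
  the ankle) must be carried during swing; its gravitational plus
  pendulum-inertial moment is windowed to swing and applied as
  dorsiflexion-directed demand (gravity plantarflexes the hanging foot, so
  the dorsiflexors carry the device), linear in the sole mass. The 1.5 kg
  cuff acts proximal to the ankle and contributes no ankle moment. NA is
  therefore the costliest condition (≈ +1% calf MC here).
- **OA** — ideal actuator free to act in both directions; its torque
  trajectory, mass-normalized, *is* the optimal assistance strategy.
- **PA** — a four-parameter template profile applied as exogenous torque,
  subtracted from the plantarflexion demand before solving.

## Metabolic model

The per-muscle instantaneous rate is a documented three-term surrogate of
muscle energetics:

    Ė = m·α_AM·a² + m·β_S·a·max(−v, 0) + max(0, −F·v·L_opt)

(activation/maintenance heat, shortening heat, positive mechanical work;
m = muscle mass in kg, v = normalized fiber velocity). The cycle total is
the trapezoidal time integral of summed rates divided by body mass and gait
duration (W/kg), calf muscles only — no basal metabolism, no muscles
outside the ankle. The coefficients are calibration constants fixed once:
with `work_scale = 1` the work term contributes 0.317 W/kg at 1.3 m/s
(no-exo, mean subject), and α_AM = 2650 W/kg, β_S = α/10 = 265 were chosen
so the unassisted calf total is 1.6 W/kg there — the scale at which a ~50%
optimal-assistance reduction corresponds to ≈ 0.8 W/kg. All condition
comparisons are relative and insensitive to this overall scale.

## Profile template and matching

The template is the unique pair of cubics with f(t₁) = 0, f(t₂) = τ_peak,
f(t₃) = 0 and zero slope at all three knots, realized in Hermite closed
form (the smoothstep 3s²−2s³ and its mirror); the eight boundary
constraints hold to machine precision and the curve is C¹. Raw OA curves
are cleaned by zeroing the dorsiflexion portion (the device assists
plantarflexion only; reflecting instead of zeroing is available behind a
flag), zero-lag 6th-order Butterworth low-pass filtering at 10 Hz
(forward–backward, sampling rate = 101 samples over the cycle duration,
cutoff clamped to 0.45× Nyquist), then full-wave rectification — a no-op on
the already non-negative signal except for filter ringing.

Template matching minimizes the sum of squared differences over the four
parameters: a coarse grid over knot triples in 2% steps (the optimal peak
for fixed knots is closed-form), Nelder–Mead refinement from the three best
starts with ties broken toward earlier start times, and a final
trust-region least-squares polish. Round-trip identity holds to better than
1e-6 on the parameter box; curves whose maximum stays below 0.01 Nm/kg
return a "no assistance" sentinel (None).

## Network and training

A fully connected 13→32→24→12→4 ReLU network maps the feature vector (sex
binary, mass, height, BMI, thigh/calf/foot/torso/pelvis dimensions, speed,
stride length, cadence, heel clearance) to (τ_peak, t₂, t₁, t₃). Inputs and
targets are z-standardized with training-split statistics so the four
heterogeneous targets contribute comparably to the L1 loss (mean per batch
for optimizer stability; scale-equivalent to the sum). Training: Adam,
initial learning rate 1e-3 halved after 10 plateau epochs, batch 64,
dropout 0.1 (inverted), L2 weight penalty λ = 1e-3, up to 200 epochs with
early stopping (patience 20) on a single seeded 80/20 shuffled split, best
validation weights restored. Initialization is uniform fan-in. The network,
backpropagation and Adam are implemented directly on numpy arrays; every
stochastic element derives from one seeded generator, so training is
bit-reproducible.

Transfer learning fine-tunes *all* layers for 100 epochs at 0.1× the
initial learning rate using only a new subject's extreme-speed (0.5 and
1.8 m/s) cycles; the standardization statistics stay frozen and a contract
guard rejects fine-tuning data at any other speed (leakage protection).
Inference clips times to [0, 100] and re-orders them if t₁ < t₂ < t₃ is
violated, flagging the sample.

## Evaluation

Per-feature accuracy is R² = 1 − SS_res/SS_tot. Shape similarity uses the
point-wise profile distance (RMS of sample-wise differences, Nm/kg) and the
symmetric Chamfer distance on (phase/100, torque/scale) point sets with
scale = the joint maximum of both curves. Because the normalization behind
published distance tables is not part of this package's contract, only
orderings of these distances (e.g. ground-truth-vs-predicted ≤
simulated-vs-predicted) are meaningful across implementations. A two-way
ANOVA helper (condition × speed) is provided as evaluation plumbing.

## Problem sizes and numerical choices

The default pipeline configuration runs 4 training and 2 test subjects at
42 cycles each; the scaled-down assistance study uses 2 subjects × 3 speeds
(1.0/1.3/1.6 m/s) × 5 noise-free cycles. These sizes keep a full run in the
minutes range on one CPU while exercising every stage; all counts are
configuration fields and scale linearly. Solver tie-breaking is
deterministic (lowest index first via the sorted-breakpoint solve); the QP
balance tolerance is 1e-6 Nm (achieved at ~1e-12); template fitting uses
xatol 1e-8 / fatol 1e-14; degenerate inputs (all-zero curves, zero-demand
cycles, empty datasets) are defined behaviors, not errors, except where a
contract requires rejection (degenerate knots, non-positive durations,
infeasible demand).

## Known limitations

- One degree of freedom: no knee/hip coupling beyond the gastrocnemius
  floor, no pelvis residuals, unilateral only.
- Prescribed kinematics: assistance does not alter the gait itself, so the
  idealized reductions exceed what experiments report; printed experimental
  reductions act as lower bounds in the acceptance checks.
- The metabolic surrogate preserves relative comparisons, not absolute
  physiology; its coefficients encode one calibration point.
- The synthetic population is narrower than real cohorts (no age effects;
  landmark trends are linear in speed by construction).
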