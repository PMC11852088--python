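# Methods

This note documents the model the package implements, the parameter
choices that matter, the numerical decisions, and what the bundled tests
do and do not establish.

## The hierarchy

### High level: optimal feedback control on an internal model

Motor decisions are made on a deliberately simple internal model, not on
the biomechanical plant: a planar point mass driven by two abstract
muscles that can push and pull,

    m ẍ = aₓ F_max,     τ ȧₓ = uₓ − aₓ     (and likewise in y),

discretized by forward Euler at the 5 ms control clock (an exact
zero-order-hold discretization changes the transition matrix only in
O(Δt²) terms and none of the package's behavior; forward Euler is used
because the iterative gain recursions in this model family are habitually
derived on it). The state is target-relative, so the dwell-phase state
penalty Q = I₆ literally penalizes residual position, velocity *and*
abstract activation at the target; R = I₂.

Motor noise is signal-dependent: each command channel injects noise
through the input matrix with standard deviation 0.2·|uᵢ| (two
independent scalar channels — the simplest structure consistent with
noise whose amplitude scales with the signal). Because of this term the
controller and estimator are coupled: the feedback-gain backward pass
carries a second cost-to-go matrix for estimation error, and the
Kalman-gain forward pass carries the closed-loop state covariance.
The two passes are alternated until the largest gain change falls below
1e-9 (typically 3–5 iterations; hard cap 500). With the multiplicative
scale and the delay set to zero both recursions collapse *exactly* to the
finite-horizon LQR Riccati recursion and the standard Kalman recursion;
the test suite asserts agreement with independently coded textbook
versions to 1e-8.

Default parameters: m = 3 kg, τ = 30 ms, F_max = 1000 N, Δt = 5 ms,
N = 221 steps (1 s transport + 21-step dwell), sensory delay d = 50 ms
(10 steps), additive process noise diag(2e-7), sensory noise diag(1e-6),
multiplicative scale diag(0.2), estimation noise diag(1e-9). The
estimation-noise covariance is specified on the two command channels and
enters the estimate through B — the estimate itself is 6-dimensional, and
injecting η through the command channels is the only dimensionally
consistent reading of a 2×2 covariance.

**Delay handling.** Sensory feedback arriving at step k measures the
state at step k−10. The belief keeps a ring buffer of the last 10 raw
measurements and applied commands; a Kalman filter runs on the *delayed*
timeline (innovation = oldest buffered measurement minus the delayed
estimate), and the current-time estimate is the forward prediction of the
delayed estimate through the buffered commands. Incrementally this is
X̂⁺ = A X̂ + B u + A¹⁰ K_j ν, i.e. the filter equation with a
delay-propagated gain. For a linear plant this prediction is exact, keeps
the estimate 6-dimensional, and reduces to the ordinary filter at d = 0.

### Mid level: synergies

The synergy set is learned offline, once per arm:

1. For 16 force directions equally spaced on the circle, compute the
   minimum-norm activation vector producing that force isometrically at
   the reference posture (a non-negative QP: min ‖a‖² s.t.
   J⁻ᵀ Rᵀ diag(fl·F_max) a = F, 0 ≤ a ≤ 1), at 25 % of the per-direction
   maximum feasible magnitude — forces comfortably inside the feasible
   polytope where the load-sharing solution is smooth.
2. Factor the 6×16 activation matrix with non-negative matrix
   factorization into 4 components (`nndsvda` initialization, so the
   result is deterministic), normalize each synergy to unit maximum
   element, and push each through the isometric statics to obtain its
   hand-force basis vector.

Four synergies reconstruct the optimal activations with R² ≈ 0.96 and
their force vectors positively span the plane, so every commanded
direction decomposes with zero residual. Online, the basis is recomputed
at the current posture each step (the muscle geometry changes materially
over a 25 cm reach); a `frozen_basis` switch restores the
fixed-motor-memory reading. The commanded task force is u·F_max plus
J⁻ᵀ·C(q,q̇)q̇ — the arm's velocity-product torques mapped to the hand —
so the point-mass internal model is not asked to know about Coriolis
accelerations. Excitations are clipped to [0, 1]; clipping engages only
for commands far outside the calibration range.

### Low level: musculoskeletal arm

Six straight-line Hill-type muscles (shoulder mono-articular pair, elbow
mono-articular pair, bi-articular pair) over a 2-link arm in a horizontal
plane. Active force–length is a Gaussian bell of width 0.4 around the
optimal length (set, per muscle, to the path length at the reference
posture); force–velocity is the Hill hyperbola for shortening
(fv(−v_max) = 0, curvature constant 0.25) and a saturating branch rising
to 1.5 for lengthening; v_max = 10 l₀/s. No tendon compliance. Muscle
paths are straight origin–insertion lines; moment arms are the exact
analytic length gradients (verified against finite differences at 1e-6).

The bundled fixture (`data/arm_fixture.yaml`) is a synthetic stand-in
parameter set. Segment lengths (0.30 / 0.33 m) follow anthropometric
tables; masses and inertias (3.0 / 2.5 kg, 0.08 / 0.13 kg·m²) sit at the
heavy end of those tables **deliberately**: they give the arm an endpoint
inertia of 2.7–4.3 kg across directions at the start posture, bracketing
the internal model's 3 kg point mass. This is an internal-model
consistency requirement, not a tuning knob — the hierarchy presumes the
brain's abstraction is calibrated to the body it controls, and with a
much lighter plant the loop gain implied by the fixed high-level
parameters is several times too high, which the 50 ms delay converts into
oscillatory instability. Muscle attachment points were placed to give
moment arms of 2–5 cm with correct agonist/antagonist signs across the
workspace; F_max between 600 and 800 N. All values are overridable, and
no test depends on the specific numbers, only on their qualitative
structure.

### Robot, coupling, environment

The robot is a symmetric 2-link arm (0.3 m, 0.5 kg, COM at mid-link,
5e-3 kg·m² per link), base placed 0.75 m anterior of the shoulder so that
all scenario start/target points lie well inside both workspaces. The
hand–end-effector attachment is revolute — transmits force, not torque —
implemented as a 2-D position constraint solved at acceleration level
with Lagrange multipliers; the multiplier *is* the interaction force, so
action–reaction is exact by construction. Baumgarte stabilization
(α = β = 20 s⁻¹) keeps numerical drift of the constraint below 1e-8 m
over full simulations (asserted < 1e-6 m). Curl fields apply
F = b·[[0,1],[−1,0]]·v at the hand.

### Closed loop

One 5 ms tick, in fixed order: read hand kinematics → compute u from the
current belief → expand to excitations → obtain robot torques → update
the belief with the (delayed) measurement → integrate the plant one RK4
step with excitations and torques held. The measurement's kinematic
channels come from the plant's forward kinematics; the two
abstract-activation channels are the internal model's own propagated
activations (a self-consistent readout — only hand position and velocity
are sensed from the body). The command is computed *before* the belief
update so that u_k = L_k X̂_k and X̂_{k+1} uses u_k, matching the filter
equations.

## Human-aware control

At every tick the robot controller rolls the complete closed-loop human
model (gain schedules indexed by global time, held at their terminal
values past the horizon) forward N_p = 50 steps under a candidate torque
profile T(k) = β₀ + β₁k + β₂k² per joint, scoring it by the mean squared
excitation. The 6 coefficients are optimized by bounded L-BFGS-B with
finite-difference gradients from the better of {zero profile, previous
solution shifted one step}, with a budget of 40 objective evaluations per
tick; the returned profile is by construction never worse than either
start. Coefficient bounds (|β₀| ≤ 20 N·m, higher-order terms bounded so
their horizon contribution stays ≤ 10 N·m each) exist because a pure
effort objective with unbounded torques is ill-posed; the torques the
task actually elicits stay below 2 N·m, far from the bounds.

The rollouts dominate the compute (≈ 45,000 full-hierarchy simulations
per movement), so they run through a numba-compiled kernel that replicates
the reference step function; the test suite asserts the two agree to
float precision over whole horizons, from rest and from mid-movement
snapshots. With the kernel, a full 221-step human-aware scenario takes
~15 s; the test suite also exercises the scenario at a shortened
121-step horizon where speed matters more than duration.

The impedance baseline renders F = k_p(x_ref − x) + k_d(ẋ_ref − ẋ) at the
end-effector (k_p = 50 N/m, k_d = 10 N·s/m) toward the stored free-reach
trajectory advanced by 50 ms (hold-last-sample beyond the end).

## Metrics

Terminal error; straightness (peak lateral deviation from the
start–target line over reach distance); time-of-peak-speed fraction
(first maximum); effort (mean over the movement of |e|²); co-contraction
(mean over time and the three flexor/extensor pairs of the pairwise
minimum excitation, compared against the pairwise maximum);
signed lateral area between the path and the straight line.
Field-induced deflection is additionally measured relative to the
same-direction null-field trajectory, the standard referencing in
force-field studies: the arm's intrinsic inertial curvature (the endpoint
inertia of a 2-link arm is anisotropic, so straight-line force commands
produce slightly curved paths, as in human data) is of the same order as
the b = ±3 N·s/m field effect, and only the baseline-referenced area
isolates the field's contribution. Speed profiles are called
single-peaked if they rise to their maximum and fall monotonically up to
fluctuations below 1 % of the peak (the dwell phase settles with
sub-millimeter-per-second ripples).

## What the simulations do and do not show

All headline runs are noise-free (single deterministic trials);
sensorimotor noise can be switched on with a seed, and seeded runs are
bitwise reproducible. The synthetic conditions reproduce qualitative
signatures of human reaching — straight paths, bell-shaped speed
profiles, reciprocal muscle use, curl-field deflection with return to
target, effort increase under a passive load, effort reduction under
predictive assistance. They do not constitute a fit to any experimental
dataset: the arm fixture is synthetic, reflexes and limb stiffness are
absent, the internal model never learns (no adaptation across trials),
and the human-aware controller reads the human's internal state directly
rather than estimating it from measurable signals. Co-adaptation,
moving-horizon estimation of user intent, 3-D or redundant kinematics,
and hardware deployment are out of scope.

## Numerical choices, in one place

- Forward Euler for the internal model (ZOH documented above); RK4 at
  5 ms for all plants; excitations and torques zero-order-held per tick.
- Gain iteration: tolerance 1e-9 on the max gain change, cap 500.
- Activation states clipped to [0, 1] after each integration step
  (RK4 can overshoot the invariant manifold by O(Δt⁵)).
- NNLS via the Lawson–Hanson solver (scipy) in the reference path and an
  enumerated KKT active-set solver (supports of size ≤ 2 for a 2-row
  system) in the compiled kernel; both agree with an exhaustive QP oracle
  to 1e-10.
- Baumgarte constants 20 s⁻¹; coupling initialized exactly consistent by
  closed-form inverse kinematics (human elbow counterclockwise, robot
  elbow on the branch away from singularity).
- The static load-sharing QP uses SLSQP with an equality constraint on
  the achieved force (residual required < 1e-6 N, typically < 1e-9).
- Ties in the peak-speed time go to the first maximum.
- Degenerate inputs: zero-length muscle paths, unreachable IK targets,
  non-PSD covariances, dwell ≥ horizon, and out-of-schedule gain indices
  all raise informative errors rather than propagating.
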