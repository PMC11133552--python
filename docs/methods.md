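# Methods

This note documents the model, the numerical choices, and the design
decisions behind `posturesim`, at the level of detail a user needs to
interpret (and distrust appropriately) its output.

## Skeletal model

The skeleton is a planar (sagittal) seven-segment chain: one trunk–pelvis
segment (head, arms and torso lumped) and mirrored thigh/shank/foot
pairs.  Generalized coordinates are pelvis translation (x anterior, z
up), pelvis tilt, and hip/knee/ankle angles shared by both legs — six
effective degrees of freedom.  Symmetry is implemented by multiplicity:
leg segments, muscles, feet and their contact forces enter the dynamics
twice, rather than by halving the model, so contact geometry and ground
reaction magnitudes stay honest.

Orientations are cumulative (trunk = tilt, thigh = tilt + hip, shank =
thigh + knee, foot = shank + ankle), positive counter-clockwise.  With
this convention the standard initial standing posture — pelvis tilt
−10°, hip flexion 20°, knee −20°, ankle 10° — puts the foot exactly flat
on the ground.  Angles are degrees at every public interface and radians
internally.

The equations of motion are assembled from analytic COM Jacobians
(`M(q) q̈ + h(q, q̇) = Q`, with `M = Σ m J᙭J + I ww᙭`), solved directly at
each evaluation; locked-coordinate variants (e.g. the ankle-strategy
model) solve the reduced system with locked coordinates at zero
acceleration.  The Jacobians, gravity terms and bias forces are verified
in the tests against a hand-derived compound-pendulum closed form
(agreement to 1e-6 relative), central finite differences of the
potential energy, and a passive-swing energy-conservation check
(drift < 0.1% per second at the default integrator resolution).

Anthropometry defaults to a 75 kg / 1.75 m adult with de Leva-like
segment fractions; the cited-literature values are not part of any test —
tests use toy configurations and scale-invariant properties, and every
parameter is overridable via config.

The head point — the location whose kinematics feed the vestibular and
visual pathways — is a fixed point on the trunk axis, by default 0.72 m
above the hip (roughly eye level for the default anthropometry).  Its
location is a free modeling choice exposed in config; nothing in the
model pins it more precisely.

Passive joint stops (soft end-range torques, 300 N m/rad with 2 N m s/rad
damping outside hip (−30°, 120°), knee (−140°, 0°), ankle (−50°, 40°))
represent the ligamentous end-range resistance every musculoskeletal
simulator ships; without a knee hyperextension stop the unoptimized
model snaps through the straight-knee configuration, which no skeleton
does.

## Muscles

Nine Hill-type muscles per leg (GLU, HAM, IL, RECT, BFSH, VAS, GAS, SOL,
TA; HAM, RECT and GAS biarticular) with a rigid tendon: fiber state is
algebraic in the joint angles, which keeps the state small and single
shooting robust.  This is a deliberate simplification of the
elastic-tendon formulation; its main consequence is slightly stiffer
high-frequency muscle dynamics.

Musculotendon geometry is defined entirely by moment-arm functions
(constant or linear in the joint angle): normalized length integrates
`dL/dθ = −r(θ)` exactly from a configured reference length at the
reference posture, so moment arms and length signals can never be
inconsistent.  Default moment arms and `F_max`/`l_opt` values are in the
range of the standard lower-limb literature, lumped per functional
group.

Curves: active force–length is a Gaussian of width 0.45 peaking at
optimal length; force–velocity is the standard hyperbolic form, zero at
maximal shortening (v_max = 10 l_opt/s), one isometrically, saturating
at 1.5 for lengthening (eccentric force enhancement is retained because
removing it removes a physical damping pathway); passive force is
quadratic above optimal length.  Activation follows first-order dynamics
with τ_act = 10 ms and τ_deact = 40 ms (standard Hill-model practice;
not printed quantities, configurable).

## Contact

Two Hunt–Crossley spheres per foot (heel, forefoot): normal force
`k δ^n (1 + c δ̇)` clamped at zero (no adhesion), with defaults
k = 4·10⁵ N/m^1.5, n = 1.5, c = 1 s/m — about 6 mm static penetration
under body weight — and regularized Coulomb friction
`−μ F_n tanh(v_rel/0.05 m/s)`, μ = 0.9.  The platform is kinematically
prescribed (infinite mass) and the ground plane translates horizontally
with it, so platform motion perturbs the model through friction.  The
COP is the normal-force-weighted mean of the loaded contact points,
flagged invalid when total load is below 1 N and excluded from range
statistics.

## Controller

Excitations follow the feedforward-plus-three-pathway law given in the
README.  Numerical/design points:

* **Units.** The gains act on SI/radian-valued signals (normalized
  muscle signals, COP and head position in meters, orientation in
  radians).  The ±3 gain bounds are only physiologically meaningful on
  that scale; degrees appear solely at the config and output interfaces.
* **Delays** are lumped (transmission + processing) per muscle and
  modality, exact multiples of the 5 ms control step, implemented as
  pre-filled ring buffers that return the sample from exactly t − τ.
  No separate efferent delay is added.
* **COP feedback** is foot-relative: the signal is the COP position
  relative to the current midpoint between the heel and forefoot contact
  points (cutaneous sensing is foot-borne), so the reference `x_cop,0`
  is that midpoint by construction and defaults to zero offset.
* **Noise** (`k_noise = 0.0005 + 0.0001·|s|`) uses the absolute signal
  amplitude so negative-valued sensors are handled; sensor noise enters
  before the delay buffer (transduction noise), actuator noise after the
  excitation clamp, followed by a re-clamp.  All draws come from streams
  derived from one seed.
* **Clamping.** The summed excitation is clamped to [0, 1]; whether the
  original control law clamps is not specified anywhere, but unbounded
  excitation is unphysiological and the clamp is what simulation
  frameworks do.
* **Acceleration sensing.** Head linear/angular accelerations sensed at
  control step k use the accelerations from the last integrator stage of
  step k−1 (half a control step stale) instead of re-solving the
  dynamics; at 200 Hz this is far inside the 125–150 ms vestibular
  delay.

## Simulation

200 Hz control rate; within each 5 ms step the coupled skeleton +
activation ODE is integrated with RK4 over 10 sub-steps (0.5 ms), which
the stiff contact demands.  Runs last 75 s; evaluation metrics use the
15–75 s window (the first 15 s are start-up transient), while the
optimization cost integrates the full horizon — the cost window is not
restricted anywhere, so the full window is the default and it is
configurable.  A fall (COM below 60% of its initial height) terminates
the run; a non-finite state is recorded as a fall with a distinct flag.
The initial pelvis height is set so the contact spheres start at their
static penetration, carrying exactly body weight, which removes the drop
transient.

## Optimization

CMA-ES (a compact standard implementation, validated on quadratics in
the tests) searches the normalized unit box mapped to the bounds: gains
±3, feedforward [0.001, 0.2], offset lengths [0.1, 2]; candidates are
clipped to the box (projection).  Each candidate is scored by one
forward simulation; all candidates within a generation share one noise
seed so ranking reflects parameters rather than noise realizations.
Six independent seeded restarts replace the framework-internal
fitness-prediction restart scheduler of the original tooling.  Stopping:
mean best-cost improvement over a sliding 20-generation window below
1e-5, or a generation cap (the averaging window of the stopping rule is
not specified anywhere; 20 generations is this package's choice).

The binary joint-limit indicators are implemented as the *fraction of
the costed window* spent outside the range: this reproduces the binary
values at the extremes (0 when never violated, 1 when violated
throughout) and gives the optimizer a graded signal in between.

**Initial guess.**  Feedforward excitations are computed from the
model's own statics: the joint torques required for zero joint
acceleration at the settled posture, distributed over the muscles by
non-negative least squares with a small ridge.  Feedback gains apply the
50:33:17 proprioceptive : visual : vestibular weighting of healthy
sensory integration as per-modality scale factors (stretch gain = 0.50·B,
summed visual position+velocity gains = 0.33·B, orientation gain
magnitude = 0.17·B, with B = 3 by default), with signs chosen so each
pathway opposes the sway it senses.  With these defaults the
ankle-strategy variant stands for the full 75 s before any optimization.

**Problem sizes.**  The reduced-scale searches exercised by the tests
use the ankle-strategy variant (hip and knee locked), 10 s horizons,
populations of 4–6 and single-digit generation counts — the package's
chosen desk-scale demonstration of the pipeline.  Full six-DOF standing
is a much harder search problem: the fall term of the cost is binary, so
CMA-ES receives no gradient toward standing while every candidate falls,
and discovering a standing basin for all 99 parameters requires the
full-scale protocol (long horizons, default populations, hundreds of
generations, six restarts).  That search is exposed
(`multi_seed_optimize` with default `OptConfig`) but is not run in the
test suite, and unoptimized full-model parameters fall within a few
seconds — which the falsification test turns into a feature: standing
is demonstrably produced by the controller.

## Evaluation

ROM is max − min over the window; RMSE linearly resamples the reference
onto the simulation grid first (the resampling scheme is this package's
choice); COP range uses valid samples only and is reported in mm.  EMG
preprocessing is zero-phase: 20–500 Hz band-pass (order 4, upper edge
capped below Nyquist with a warning for low-rate input), full-wave
rectification, 6 Hz third-order Butterworth low-pass.  Reference series
are delimited text with a named-channel header; sign conventions of
external files are the supplier's responsibility and are declared in
that header, not auto-inferred.

## Synthetic data and what the tests do not show

The fixture generator produces analytically transparent synthetic
trajectories (a linearly sinking COM, constant limit-violating joint
angles, sinusoidal references) — they exercise the cost and metric
definitions exactly, but contain none of the spectral structure of real
sway.  The simulator's own output emulates quiet-standing sway only as
far as the modeled noise (signal-dependent sensor/actuator noise) goes:
breathing, cardiac ballistics and exploratory drift are absent, so
simulated sway amplitudes at default noise are near the lower edge of
physiological ranges.  Passing tests therefore establish the mechanics,
the control law, the cost and the search machinery — not fidelity to any
particular experimental dataset.

## Known limitations

* Sagittal plane only; no medio-lateral balance, no stepping responses.
* Rigid tendon; no pennation; no muscle wrapping.
* Symmetric control: left/right asymmetries cannot be represented.
* The platform transmits motion through friction only (flat ground,
  horizontal translation); vertical or rotational perturbations are out
  of scope.
* Sensory fusion is a weighted sum with fixed gains — no optimal
  estimation, no frequency-dependent reweighting.
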