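# Methods

## Model

Each of the six legs (L1/L2/L3 left fore/middle/hind, R1/R2/R3 right)
carries one phase oscillator

    dphi_i/dt = omega + f_i,

with swing intention for `phi in [0, pi)` and stance intention for
`phi in [pi, 2*pi)`.  There is no direct coupling between oscillators: all
coordination is carried by the mechanics, through the vertical ground
reaction forces `N_i` (newtons).

The feedback `f_i` is the gradient of a *Tegotae* function — a scalar
scoring the consistency between what the controller intends and what the
leg feels:

    T_i  = sigma1 * T_i1 + sigma2 * T_i2
    T_i1 = (-sin phi_i) * N_i                      (own leg: loaded stance is good)
    T_i2 = sin phi_i * (1/n_L) * sum_j k_j * N_j   (neighbors: swing while they carry)
    f_i  = dT_i / dphi_i
         = (-sigma1 * N_i + sigma2 * (1/n_L) * sum_j k_j * N_j) * cos phi_i

The neighbor set of a leg contains the ipsilateral legs of adjacent rank
and the contralateral leg of the same rank (`n_L` = 2 for fore/hind legs,
3 for middle legs).  Neighbor forces are weighted by their relation to the
target leg: anterior `k_a`, posterior `k_p`, contralateral `k_c`.  The
anterior-posterior asymmetry (`k_a > k_p`) is what stabilizes the
speed-dependent gait transition.

Motor targets per leg (degrees): `theta_yaw = -A cos phi` sweeps the leg
fore-aft; `theta_roll = B sin phi` lifts it during swing and
`theta_roll = B' sin phi` (negative) presses it down during stance.

### Parameters

| symbol  | meaning                              | default | units   |
|---------|--------------------------------------|---------|---------|
| omega   | intrinsic angular velocity           | 2.0     | rad/s   |
| sigma1  | own-leg Tegotae gain                 | 0.2     | rad/(s N) |
| sigma2  | neighbor Tegotae gain                | 1.2     | rad/(s N) |
| k_a     | anterior neighbor weight             | 0.7     | –       |
| k_p     | posterior neighbor weight            | 0.1     | –       |
| k_c     | contralateral neighbor weight        | 0.2     | –       |
| A       | fore-aft sweep amplitude             | 15      | deg     |
| B       | swing lift amplitude                 | 20      | deg     |
| B'      | stance press amplitude               | 5       | deg     |

These are the gains the original robot experiments used; the five standard
scenarios (`steady_walk`, `speed_transition`, `load_adaptation`,
`amputation`, `ablation_sigma2`) change only `omega` (fixed 2.0, or ramped
linearly 2.0 -> 4.0 rad/s over 40–42 s), `sigma2` (1.2 or 0), the 500 g
hind load, and the amputation set {L2, R2}.  Trials last 50 s from
independently drawn uniform-random initial phases; experiments run 10
trials.  Trial streams derive from `SeedSequence(seed, spawn_key=(trial,))`
so results are order-insensitive and exactly reproducible.

## Body surrogate

The force-generating body replaces a 0.40 m x 0.30 m, 2.4 kg hexapod robot
with a quasi-static rigid body on unilateral vertical springs — a
"treadmill abstraction" with no fore-aft travel, inertia, impacts or
friction.  Components:

- **Foot kinematics.**  The commanded roll angle maps to vertical foot
  clearance as `drop = L * (1 - sin theta_roll)` below the attachment
  (leg length L = 0.20 m): `theta_roll = 0` puts the tip exactly at ground
  level for a body standing at height L, positive angles lift the tip,
  negative angles press it below the plane.  Only vertical clearance
  matters to the feedback, so the fore-aft sweep does not enter the
  contact model.  Feet exactly at ground level count as contact at
  touchdown (`phi = pi`) but not at liftoff (`phi = 0`).
- **Load sharing.**  A 3-DOF (heave/pitch/roll, small-angle) equilibrium
  solve finds the pose where spring forces `N_i = max(0, k * penetration)`
  balance the weight `(M + m_load) * g` with zero pitch/roll moment about
  the combined center of mass (lever rule for added loads).  The active
  contact set is found by fixed-point iteration on the 3x3 linear balance
  system; the problem is convex, so the force distribution is unique and
  `grf_step` is a pure function — identical inputs give identical forces.
- **Tipping.**  If the stance-intention feet cannot support the center of
  mass, the body tips until lifted feet are pressed onto the ground; the
  solve is then repeated with all intact legs as candidate contacts.  Only
  when no leg intends stance at all (or no balanced state exists) is the
  step flagged as a fall, with all forces zero.  Without this second stage,
  transient unsupported configurations zero the feedback for long
  stretches and coordination cannot form — a physical robot's ground
  forces never vanish that way.
- **Contact stiffness.**  `contact_stiffness = 300 N/m` is the effective
  *whole-leg* vertical compliance (series combination of the leg's
  shock-absorbing springs, structure and the load-spreading role that body
  dynamics play on a physical machine).  It is deliberately soft: the
  elastic penetration at typical loads (~8 N -> ~27 mm) must be comparable
  to the commanded stance press depth (~17 mm at `B' = 5 deg`), so that
  several stance legs share load.  A stiff contact (thousands of N/m)
  makes the quasi-static solve winner-take-all — the 2–3 deepest-pressed
  feet carry everything, stance rasters collapse, and no insect-like gait
  forms.  The stiffness is configurable; the experiments are robust over
  roughly 150–500 N/m, with the tetrapod/tripod boundary sharpest near
  300 N/m.
- **Attachments.**  Fore/middle/hind legs attach at x = +0.15/0/-0.15 m,
  left/right at y = +/-0.15 m about the body center (configurable).

## Integration

Fixed-step explicit Euler, `dt = 1 ms` (classical RK4 selectable).  Forces
are held constant over each step (zero-order hold, as in a sensor-sampled
control loop).  The dynamics are slow (`omega <= 4 rad/s`, feedback terms
of the same order), so 1 kHz Euler is far inside its stability margin;
halving `dt` changes trial outcomes only at rounding level.  State is
recorded every 5 steps (200 Hz), ample for gaits with periods above 1.5 s.

## Gait analysis

- **Stance detection.**  A leg is in stance where its vertical force is at
  least 10 % of the trial's maximum force (the rule that yields a 1.5 N
  threshold on a robot peaking near 15 N); an absolute-threshold mode is
  available for external force recordings.
- **Events.**  Touchdowns are rising edges of the stance raster — sensed
  contact, not the oscillator's intention; both are exported so their
  mismatch is observable.  Before event analysis the raster is
  de-chattered (morphological closing then opening, 0.15 periods): tipping
  transients otherwise inject sub-100 ms force spikes that create spurious
  touchdowns.
- **Relative phases.**  Pairwise touchdown lags as circular means over
  cycles, with the period estimated as the median inter-touchdown
  interval.
- **Labels** (tolerance `delta = pi/6`, configurable):
  - *tripod* — triads (L1,R2,L3) and (R1,L2,R3) each cluster within
    `delta` of their own circular-mean touchdown phase, and the two
    cluster centers are anti-phase.  The centroid form (rather than
    all-pairs in-phase tests) matters because the converged tripod keeps a
    metachronal remnant of ~40 deg pairwise spread.
  - *tetrapod* — ipsilateral touchdown order hind -> middle -> fore on
    both sides in at least 75 % of cycles (the behavioral definition; lag
    spacing is not enforced), with a median of at least three legs loaded.
  - *wave* — same ordering with mean duty factor above 0.75.
  - *trot / L-S walk* (four intact legs) — contralateral fore and hind
    pairs anti-phase with diagonal partners landing within the following
    half-cycle; sub-label `trot` for simultaneous diagonal touchdowns,
    `ls_walk` for the staggered order L1, R3, R1, L3.
  - *other* — anything else, including the one-sided metachronal patterns
    the ablated controller produces.
- **Duty factors** are stance fractions over the trailing six periods.
  Labels for ramp scenarios are assessed over the final six periods
  (post-ramp) and the six periods preceding the ramp start (pre-ramp).

## What the surrogate does and does not show

The closed loop reproduces the robot's all-or-nothing trial outcomes: slow
walking converges to the tetrapod gait from any initial phases; the speed
ramp switches it to a tripod; a 500 g hind load suppresses that switch and
raises hind duty factors (fore duty drops, middle rises — the same pattern
the robot showed); middle-leg amputees self-organize a quadruped trot /
L-S walk; and removing the neighbor term (`sigma2 = 0`) destroys
robustness, leaving mostly non-insect patterns with opposite metachronal
directions on the two sides.

Known limitations:

- Quasi-statics has no inertia, impacts, slipping or terrain; horizontal
  forces are a diagnostic estimate only and are never fed back.
- Force profiles are bell-shaped in penetration rather than plateau-like,
  so the 10 %-threshold stance bands are edge-trimmed and measured duty
  factors (~0.4–0.65) sit below insect-typical values.
- Duty factors do not decrease uniformly with omega: in the quasi-static
  loop duty is set purely by the feedback phase portrait and sits near 0.5
  at both speeds.  The load- and amputation-induced duty *increases* are
  reproduced (sign and significance); the speed-duty trend of real
  walkers is not.
- The tetrapod's three touchdown groups are unevenly spaced (lags of
  roughly 60/120/180 deg rather than 120/120/120), another signature of
  the simplified contact mechanics.
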