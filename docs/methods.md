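# Methods

## The model

`desirmix` simulates decisions made *during* movement, when several goals
compete for a single effector.  Each candidate goal `j` owns a stochastic
optimal controller: a finite-horizon linear-quadratic regulator for a planar
point mass (state `x = (p, v)`, control `u` = force), with cost

    J_j = (x_T - x_goal)' Q_T (x_T - x_goal)  +  Σ_t u_t' R u_t

— a terminal accuracy penalty plus accumulated effort.  Backward dynamic
programming gives the goal's policy `π_j(x) = -K_t (x - x_goal)` and its
cost-to-go `V_j(x)`, the expected effort-plus-accuracy cost of committing to
goal `j` from state `x`.  Additive Gaussian motor noise enters on the
control channels; it contributes a state-independent constant to the
cost-to-go and leaves the policy unchanged.

At every re-planning step the executed control is a weighted mixture of the
per-goal policies,

    u = Σ_j  w_j(x)  π_j(x),

where the weight `w_j` is the goal's **relative desirability**: the
probability that goal `j` delivers the highest pay-off with the least
effort.  It is the product of two probabilities, renormalised across goals:

* **action component** — `P(cost_j < cost_i≠j)`, approximated by the softmax
  `exp(-V_j/λ) / Σ_i exp(-V_i/λ)` over the costs-to-go (computed max-shifted;
  exactly invariant to adding a constant to every cost);
* **goods component** — `P(reward_j > reward_i≠j)`.  When magnitudes are
  fixed and only receipt is chancy this is the renormalised reward
  probability.  When magnitudes are stochastic (reward 0 with probability
  `1-p`, else Normal(μ, σ²)) the comparison is between session averages over
  N trials: the difference of the two session means is treated as Normal
  with mean `p₁μ₁ - p₂μ₂` and variance `σ₁²/(p₁N) + σ₂²/(p₂N)`, evaluated
  with the Normal CDF, or with the logistic approximation of scale `S/1.6`.

Because desirability is state- and time-dependent, the same machinery
produces winner-take-all movements (one weight dominates), spatial averaging
(comparable weights pull toward an intermediate point), in-flight
corrections when a cue collapses the weights, and serial-order behavior
when the goods component encodes a timetable.

### The session-average law

The Normal session-average law above is the model's own distributional
assumption; it is not the exact law of a Bernoulli–Normal mixture average
(whose variance is `(pσ² + p(1-p)μ²)/N`).  The `montecarlo` method for the
goods component therefore samples from the model's law — it is a sampling
oracle for the analytic CDF evaluation, and the two agree to Monte-Carlo
error by construction.  Tests that compare the analytic form against
sampling use this oracle; the distinction matters if you intend to compare
against literal per-trial reward draws, which the model does not represent.

### Estimation noise and conflict

Biological estimates of the two components are imprecise.  `combine` adds
independent zero-mean Gaussian noise (s.d. `noise_sd`) to every component
value, clips each at a small positive floor (1e-6), multiplies, and
renormalises.  The floor guarantees the normalising sum is positive, so the
0/0 indeterminate form of extreme conflict — one option strictly better in
reward, the other strictly cheaper, making every noiseless product zero —
resolves by symmetry to mean weight 1/2 per option.  Noise levels of
0.02–0.05 are used in the reaching and saccade simulations; copy trials run
with zero estimation noise (see below).

### λ selection

The softmax scale is chosen per evaluation by `λ = κ · mean(costs)`
(`cost_scale` rule), which keeps the action component non-degenerate as
costs swing over orders of magnitude between far-from-goal and near-goal
states.  κ is the single sharpness knob: reach tasks use κ = 0.5, saccade
tasks κ = 1.0, copy tasks κ = 0.28.  Smaller κ approaches winner-take-all
on the cheapest goal.  A `fixed` rule is available.

## Execution: receding horizon, cues, commitment

Trials run closed-loop.  Every `replan_interval` steps (default 1) the
per-goal controllers are rebuilt from the current state with fresh
time-to-contact horizons `T_j = max(10, dist / reference_speed / dt)`, the
costs-to-go and desirabilities are re-evaluated, and the mixed control is
applied.  At a cue the weights collapse one-hot onto the cued goal.  In
saccade mode the weights freeze after `commit_fraction` (default 0.2) of
the planned duration — saccades are ballistic, with only a brief window
after onset in which competition can still resolve.  Across trials, cued
reward probabilities can be updated with a delta rule
`p ← p + α(1 - p)` (α default 0.2), the non-cued goals rescaled to keep the
vector normalised.

Defaults: dt 10 ms (reach) / 1 ms (saccade), mass 1, viscous damping 10,
reference speed 25 (reach) / 200 (saccade) length-units/s, targets at ~10
units.  Accuracy/effort weights (`Q_T = I` on position, `R = 1e-7·I` reach /
`1e-10·I` saccade, saccades with a 1e-3 terminal velocity penalty) were set
so noiseless movements end within 1% of the target distance, saccades at
rest.

## Sequential copying

Copying a polygon is a chain of vertex-to-vertex reaches whose order is
imposed through the goods component.  Traversal times of a single segment
are approximately Normal (mean μ_τ, s.d. σ_τ, estimated from 100
receding-horizon rollouts of one segment, crossing times interpolated
within the step); independent segments compose, so the arrival time at
vertex j from trial onset is Normal with mean j·μ_τ and variance j·σ_τ².
The probability that vertex j is the current goal at trial time t is

    P(vertex = j | t) = (1 - Φ_j(t)) · Φ_{j-1}(t),

with Φ_k the vertex-k arrival CDF; a completed vertex's CDF is fixed at 1
(conditioning on completion), but the windows stay anchored to the trial
clock, so later windows are flatter and overlap more.  The renormalised
window probabilities over unfinished vertices form the goods component;
per-vertex controllers supply the action component as usual.

Two execution details matter.  A vertex only counts as reached when entered
from outside its completion ball (the closing vertex of a closed shape is
coincident with the pen at onset and is excluded from competition until the
pen has left it).  Completion uses the rounded-corner tolerance `2ε`
(ε = 3% of mean segment length); the post-hoc classifier labels a corner
passed within `(ε, 2ε]` as `corner_rounding`, an out-of-order or skipped
vertex as `transposition`, in-order ε-clean drawings as `none`.

Two calibration choices compensate for the reconstructed plant being
cleaner than a biological one.  First, the fitted σ_τ is floored at
0.25·μ_τ: under purely additive motor noise with per-step feedback, arrival
times are nearly deterministic (cv ≈ 2%), and the hand-off windows need
realistic width to overlap (in biological movements the spread is dominated
by signal-dependent noise, which this plant omits by design).  Second, the
timetable runs at `tempo` 0.85 — windows 10–15% faster than the realized
single-segment average — keeping forward pressure on the sequence.
Lateness against the schedule then accumulates linearly while window widths
grow only as √j, which is what concentrates errors on the middle segments:
at 200 seeded pentagon trials the per-segment error counts are
approximately [49, 69, 47, 12, 0] — an interior peak, a cleaner first
segment, and an essentially error-free final segment (it has no successor
window competing with it).  The pooled middle-segment error rate is about
1.7× the pooled first+last rate; note the first segment is not individually
cleaner than every middle segment in this reconstruction.

## Scenario experiments

* **Desirability maps** probe the weight field on a circle (radius 85% of
  the start-to-midpoint distance, probe velocities radially outward at the
  speed of the optimal single-goal reach at 85% completion) or, for
  saccades, an ellipse centred between the targets (minor axis twice the
  start-to-centre distance, major axis twice the minor, zero probe
  velocity).  Per-goal costs at each probe are averaged over 100 noisy
  rollouts before conversion to weights.
* **Averaging saccades**: an endpoint counts as averaging when its angular
  position (seen from the start) falls strictly inside the central third of
  the inter-target sector; boundary endpoints do not count.  The separation
  sweep runs 200 trials per angle at eccentricity 10 and reports percentages
  with binomial standard errors.  Under the default saccade conditions
  (motor noise 300, estimation noise 0.05, commit fraction 0.2) averaging
  falls from ~60% at 30° separation to under 10% at 90°; the fall-off is
  steeper than gradual.
* **Hemifield bias**: targets spread at equal eccentricity over an 80°
  span; the mean signed initial heading moves toward the hemifield with
  more targets, and grows with the imbalance, purely through normalisation
  across policies.

## What the simulations do and do not show

All experiments run on synthetic task configurations; there is no fitting
to behavioral data.  Passing tests show that the probability-currency
integration reproduces the qualitative repertoire — averaging vs direct
movements, probability- and history-driven biases, the separation-dependent
global effect, serial-order hand-offs with middle-segment errors — under
one consistent parameterisation.  They do not show quantitative agreement
with human or monkey kinematics: the plant is a linear point mass without
signal-dependent noise, sensory estimation, or muscle dynamics, movement
extents and forces are in arbitrary units, and two calibrations (the
arrival-σ floor and the timetable tempo) stand in for realism the plant
lacks.

## Numerical choices

Riccati solutions are memoised by steps-to-go (gains are goal-independent
in goal-relative coordinates), so per-step re-planning costs little.
Weights are validated to sum to 1 within 1e-9.  Degenerate cases: a single
goal gets weight 1 directly; an all-zero goods vector is a validation
error for binary rewards and falls back to the imminent vertex in
sequential mode when every window's mass is in the far tail; zero reward
probability makes the session-variance undefined and routes to the
sampling oracle.  Ties in the averaging-sector classification resolve to
not-averaging; the preference-switch sweep interpolates the unique sign
change of a strictly monotone difference.
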