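# desirmix

Dynamic decision-making *during* action: per-goal stochastic optimal
controllers whose policies are blended online by a normalized probability
weight — the **relative desirability** — that folds action costs and goods
values into one currency.

## The problem

When a reacher or a saccade faces several potential targets, the brain does
not pick first and move second: it prepares actions toward all of them and
lets online information bias the competition.  Modeling this requires
integrating quantities with different units — the effort and accuracy cost
of each movement, and the probability and magnitude of each reward — while
the state changes under the ongoing action.  `desirmix` is for
computational/sensorimotor-neuroscience researchers who want a working,
testable implementation of that integration.

## The model

Each goal *j* gets a finite-horizon LQG controller for a planar point mass:
policy π<sub>j</sub>(x) and cost-to-go V<sub>j</sub>(x) for the cost
(x<sub>T</sub> − x<sub>goal</sub>)′Q<sub>T</sub>(x<sub>T</sub> − x<sub>goal</sub>) + Σ u′Ru.
The executed control is the mixture

&nbsp;&nbsp;&nbsp;&nbsp;u = Σ<sub>j</sub> w<sub>j</sub>(x) · π<sub>j</sub>(x),

with w<sub>j</sub> ∝ P(cost<sub>j</sub> lowest) · P(reward<sub>j</sub>
highest), normalized to sum to 1.  The cost term is a softmax over
costs-to-go, exp(−V<sub>j</sub>/λ)/Σ<sub>i</sub> exp(−V<sub>i</sub>/λ); the
reward term compares reward probabilities directly, or session-average
rewards through a Normal law (Φ((p₁μ₁−p₂μ₂)/S) with
S² = σ₁²/(p₁N) + σ₂²/(p₂N)), with a logistic approximation of scale S/1.6.
Small Gaussian estimation noise on both components, clipped at a positive
floor, resolves the 0/0 indeterminacy of extreme effort-vs-reward conflict
to indifference (mean weight ½ each).

One framework then reproduces: spatial-averaging reaches to equidistant
targets with in-flight correction; winner-take-all to higher-probability or
higher-reward targets; trial-history biases via a delta-rule probability
update; the saccadic *global effect* and its fall-off with target
separation; heading biases toward the hemifield with more targets; and
serial-order shape copying, where time-dependent vertex probabilities
(Normal arrival windows composing as mean j·μ, variance j·σ²) act as the
goods component and produce corner-rounding and transposition errors
concentrated on middle segments.

See `docs/methods.md` for assumptions, parameters, and calibration details.

## Worked example

Two equidistant, equiprobable reach targets; the true target (`R`) is cued
mid-flight:

```python
import numpy as np
from desirmix.experiments import reach_pair_config
from desirmix.policy_mixer import run_trial

config = reach_pair_config(separation=10.0, cue_step=20, cued_goal="R")
record = run_trial(config, np.random.default_rng(7))
print("selected goal:   ", record.selected_goal)
print("outcome class:   ", record.error_class)
print("initial heading: ", round(record.initial_heading, 1), "deg")
print("weights at step 0:", np.round(record.weights_per_step[0], 3))
print("weights at cue:   ", np.round(record.weights_per_step[20], 3))
```

prints

```
selected goal:    R
outcome class:    corrected
initial heading:  89.9 deg
weights at step 0: [0.503 0.497]
weights at cue:    [0. 1.]
```

Before the cue the two policies are nearly equally desirable (weights
≈ 0.5/0.5), so the mixture launches the hand along the bisector (90° is
straight between the targets).  The cue collapses the weights onto `R`
and the trial ends there, classified `corrected` — an averaging launch
fixed in flight.

## Command line

```bash
desirmix reach   --config cfg.yaml --trials 20 --seed 3 --out out/
desirmix saccade --config sac.yaml --trials 20 --seed 3 --out out/
desirmix copy    --shape pentagon --trials 50 --seed 3 --out out/
desirmix map     --config cfg.yaml --target R --geometry circle --out out/
desirmix sweep   --angles 30,45,60,75,90 --trials 200 --seed 3 --out out/
desirmix bias    --left 2 --right 1 --trials 100 --seed 3
```

Outputs: `trajectories.csv` (`trial_id, step, t_sec, px, py, vx, vy, ux,
uy`), `weights.csv` (`trial_id, step, w_<label>...`), `summary.json`
(endpoint, selected goal, heading, error class, seed) and a `manifest.json`
listing files with row counts.  Config files are YAML with `task`,
`dynamics`, `desirability`, `execution`, and `output` sections; see
`tests/test_cli_io.py` for a minimal example.

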