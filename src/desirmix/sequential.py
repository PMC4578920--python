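"""Serial-order control for shape copying via time-dependent vertex probabilities.

Copying a polygon is a chain of reaches from vertex to vertex in a fixed
order.  Order is imposed through the goods component: the probability that
vertex j is the *current* goal at time t is

    P(vertex = j | t) = (1 - CDF_j(t)) * CDF_{j-1}(t)

where ``CDF_k`` is the Normal arrival-time distribution for vertex k.
Segment traversal times are approximately Normal and add independently
along the chain, so vertex j's arrival time from trial onset is Normal
with j times the single-segment mean and variance.  During a trial the
windows stay anchored to the trial clock — completion events fix the
completed vertices' CDFs at one but do not re-anchor the rest — so later
vertices have flatter, more overlapping windows.  Because consecutive CDFs
overlap, the desirability of the next segment starts rising before the
current one is finished, which is what produces corner-rounding and
transposition errors, predominantly on middle segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from desirmix.desirability import DesirabilityWeights, action_component, combine
from desirmix.optimal_control import (
    ConfigurationError,
    Controller,
    DynamicsSpec,
    EffectorState,
    GoalSpec,
    build_controller,
    cost_to_go,
    default_horizon,
)
from desirmix.policy_mixer import LambdaRule, TrialConfig, TrialRecord, mixed_action

__all__ = [
    "NonArrivalError",
    "ShapeSpec",
    "ArrivalModel",
    "regular_polygon",
    "copy_trial_config",
    "estimate_arrival_model",
    "vertex_probability",
    "run_copy_trial",
    "classify_copy_error",
    "segment_error_counts",
    "chain_arrival_times",
]

# Pen pauses at corners: a mild terminal velocity penalty makes every
# segment start near rest, so segment traversal times are close to
# independent and identically distributed along the chain.
COPY_VELOCITY_WEIGHT = 1e-3


class NonArrivalError(RuntimeError):
    """A rollout failed to reach its segment end vertex within the horizon."""


@dataclass(frozen=True)
class ShapeSpec:
    """An ordered polygonal path to be copied."""

    vertices: np.ndarray  # (n, 2)
    closed: bool = True
    direction: str = "counterclockwise"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ConfigurationError("a shape needs at least 3 planar vertices")
        nxt = np.roll(v, -1, axis=0)
        if np.any(np.linalg.norm(nxt - v, axis=1) < 1e-12):
            raise ConfigurationError("consecutive vertices must be distinct")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")

    def waypoints(self) -> np.ndarray:
        """Vertices in drawing order, starting point first.

        A closed shape revisits the start, so n vertices give n segments;
        an open shape gives n - 1.
        """
        if self.direction == "counterclockwise":
            v = self.vertices
        else:  # same start vertex, opposite travel direction
            v = np.vstack([self.vertices[:1], self.vertices[1:][::-1]])
        if self.closed:
            return np.vstack([v, v[:1]])
        return v

    @property
    def n_segments(self) -> int:
        return len(self.vertices) if self.closed else len(self.vertices) - 1

    def mean_segment_length(self) -> float:
        w = self.waypoints()
        return float(np.mean(np.linalg.norm(np.diff(w, axis=0), axis=1)))


@dataclass(frozen=True)
class ArrivalModel:
    """Normal model of the time to traverse one segment, in seconds."""

    mu_tau: float
    sigma_tau: float

    def __post_init__(self) -> None:
        if self.mu_tau <= 0:
            raise ConfigurationError(f"mu_tau must be positive, got {self.mu_tau}")
        if self.sigma_tau < 0:
            raise ConfigurationError(f"sigma_tau must be >= 0, got {self.sigma_tau}")


def copy_trial_config(process_noise_sd: float = 50.0, kappa: float = 0.28,
                      **overrides) -> TrialConfig:
    """Study conditions for shape-copying trials.

    Moderate motor noise, a moderately sharp cost softmax, and no
    estimation noise on the desirability components (order pressure and
    execution noise are the error drivers in this task).  The ``goals``
    entry is a placeholder — copy trials take their goals from the shape.
    """
    from desirmix.desirability import NoiseSpec  # local: avoid cycle at import

    defaults = dict(
        goals=(GoalSpec(position=[0.0, 1.0], label="shape"),),
        dynamics=DynamicsSpec(process_noise_sd=process_noise_sd),
        noise=NoiseSpec(noise_sd=0.0),
        lambda_rule=LambdaRule(kappa=kappa),
    )
    defaults.update(overrides)
    return TrialConfig(**defaults)


def regular_polygon(
    n: int, radius: float = 6.0, start_angle_deg: float = -90.0,
    direction: str = "counterclockwise",
) -> ShapeSpec:
    """A regular n-gon centred at the origin (default: start at the bottom)."""
    angles = np.radians(start_angle_deg) + 2 * np.pi * np.arange(n) / n
    verts = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    return ShapeSpec(vertices=verts, closed=True, direction=direction)


def _copy_accuracy_weight() -> np.ndarray:
    return np.diag([1.0, 1.0, COPY_VELOCITY_WEIGHT, COPY_VELOCITY_WEIGHT])


def _segment_controller(
    dynamics: DynamicsSpec, start: np.ndarray, goal: GoalSpec, slack: float = 2.0,
    horizon_floor: int = 10,
) -> Controller:
    """Controller for one segment with slack beyond the nominal horizon."""
    T = default_horizon(dynamics, start, goal.position, floor=horizon_floor)
    return build_controller(
        dynamics, goal, int(np.ceil(slack * T)),
        accuracy_weight=_copy_accuracy_weight(),
    )


def _receding_segment_rollout(
    dynamics: DynamicsSpec,
    x: np.ndarray,
    goal_pos: np.ndarray,
    eps: float,
    rng: np.random.Generator,
    max_steps: int,
    horizon_floor: int = 10,
) -> tuple[np.ndarray, float | None]:
    """One noisy traversal to a vertex under the receding-horizon policy.

    Every step the controller is rebuilt with a fresh time-to-contact
    horizon from the current distance — the same execution scheme the copy
    trials use, so arrival-time statistics estimated here are consistent
    with what the trial loop realises.  Returns the final state vector and
    the arrival step as a float — the ball-crossing instant is interpolated
    linearly within the crossing step, so arrival times are not quantized
    to the integration grid — or None if the ball was never entered.
    """
    A, B = dynamics.system_matrices()
    sd = dynamics.process_noise_sd
    goal = GoalSpec(position=goal_pos, label="segment")
    x = x.copy()
    d_prev = float(np.linalg.norm(x[:2] - goal_pos))
    for t in range(max_steps):
        ctrl = _segment_controller(dynamics, x[:2], goal, slack=1.0,
                                   horizon_floor=horizon_floor)
        u = -ctrl.gains[0] @ (x - goal.state_vector())
        noise = rng.normal(0.0, sd, size=2) if sd > 0 else np.zeros(2)
        x = A @ x + B @ (u + noise)
        d_new = float(np.linalg.norm(x[:2] - goal_pos))
        if d_new <= eps:
            frac = 1.0 if d_prev <= d_new else (d_prev - eps) / (d_prev - d_new)
            return x, t + min(max(frac, 0.0), 1.0)
        d_prev = d_new
    return x, None


def estimate_arrival_model(
    controller: Controller,
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
    start: EffectorState | None = None,
    arrival_radius: float | None = None,
    min_sigma_frac: float = 0.0,
) -> ArrivalModel:
    """Sample segment traversals and fit the Normal arrival-time model.

    ``controller`` defines the segment (its goal and dynamics); rollouts
    run the same receding-horizon closed loop as trial execution.  Arrival
    is the first step inside the ``arrival_radius`` ball around the end
    vertex (default 3% of the segment length).  Returns the sample mean and
    s.d. of the arrival times in seconds.

    ``min_sigma_frac`` floors the fitted s.d. at that fraction of the mean.
    With purely additive motor noise the tightly corrected closed loop
    produces almost deterministic arrival times; biological arrival
    distributions (whose spread is dominated by signal-dependent noise,
    which this plant omits) are much wider, and the sequential hand-off
    windows need that width to overlap.
    """
    if n_reps < 2:
        raise ConfigurationError("need n_reps >= 2 to estimate a spread")
    rng = rng or np.random.default_rng()
    goal_pos = controller.goal.position
    if start is None:
        start = EffectorState(np.zeros(2), np.zeros(2), 0)
    if arrival_radius is None:
        arrival_radius = 0.03 * float(np.linalg.norm(goal_pos - start.position))

    times = np.empty(n_reps)
    for rep in range(n_reps):
        _, step = _receding_segment_rollout(
            controller.dynamics, start.vector(), goal_pos, arrival_radius,
            rng, max_steps=controller.horizon,
        )
        if step is None:
            raise NonArrivalError(
                f"rollout {rep} to vertex at {goal_pos} never entered the "
                f"{arrival_radius:.3g} arrival ball within {controller.horizon} steps"
            )
        times[rep] = step * controller.dynamics.dt
    mu = float(times.mean())
    sigma = max(float(times.std(ddof=1)), min_sigma_frac * mu)
    return ArrivalModel(mu_tau=mu, sigma_tau=sigma)


def vertex_probability(
    j: int, t: float, model: ArrivalModel, completed: int = 0
) -> float:
    """P(vertex j is the current goal at time t since the last completion).

    Vertex k (k > completed) is ``k - completed`` segments ahead, so its
    arrival time is Normal with ``(k - completed)`` times the single-segment
    mean and variance.  The current-goal probability is (not yet arrived at
    j) x (already arrived at j - 1), with the completed vertex's CDF
    identically one.
    """
    if j <= completed:
        raise ValueError(f"vertex {j} is not ahead of completed vertex {completed}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")

    return _current_goal_prob(j - completed, t, model)


def _chain_cdf(steps: int, t: float, model: ArrivalModel) -> float:
    """CDF of the time to finish ``steps`` more segments (0 steps: done)."""
    if steps <= 0:
        return 1.0
    mu = steps * model.mu_tau
    sd = np.sqrt(steps) * model.sigma_tau
    if sd == 0:
        return float(t >= mu)
    return float(stats.norm.cdf(t, loc=mu, scale=sd))


def _current_goal_prob(steps: int, t: float, model: ArrivalModel) -> float:
    """(not yet at the vertex `steps` ahead) x (past the one before it)."""
    return (1.0 - _chain_cdf(steps, t, model)) * _chain_cdf(steps - 1, t, model)


def _remaining_goods(
    n_remaining: int, t: float, model: ArrivalModel
) -> np.ndarray:
    """Renormalised current-goal probabilities over the unfinished vertices.

    The k-th unfinished vertex (in sequence order) is k segments of work
    ahead, clocked from the last completion event.
    """
    vals = np.array(
        [_current_goal_prob(k, t, model) for k in range(1, n_remaining + 1)]
    )
    total = vals.sum()
    if total <= 0:  # far tail of every CDF: the imminent vertex is the goal
        vals = np.zeros(n_remaining)
        vals[0] = 1.0
        return vals
    return vals / total


def _origin_anchored_goods(
    active: list[int], reached: np.ndarray, t: float, model: ArrivalModel
) -> np.ndarray:
    """Current-goal probabilities on the trial clock, widths growing as sqrt(j).

    The arrival-time distribution for vertex j composes j segment
    traversals, so on the clock that starts at trial onset it is Normal
    with mean j*mu and variance j*sigma**2 — later vertices have flatter,
    more overlapping windows, which is what makes competition (and hence
    errors) strongest for middle segments.  Conditioning on completion
    fixes a completed vertex's CDF at one; the remaining windows keep their
    original anchoring.
    """

    def cdf(k: int) -> float:
        if k < 1 or reached[k]:
            return 1.0
        mu = k * model.mu_tau
        sd = np.sqrt(k) * model.sigma_tau
        if sd == 0:
            return float(t >= mu)
        return float(stats.norm.cdf(t, loc=mu, scale=sd))

    vals = np.array([(1.0 - cdf(j)) * cdf(j - 1) for j in active])
    total = vals.sum()
    if total <= 0:  # off every window: head for the next vertex in order
        vals = np.zeros(len(active))
        vals[int(np.argmin(active))] = 1.0
        return vals
    return vals / total


def run_copy_trial(
    shape: ShapeSpec,
    config: TrialConfig,
    rng: np.random.Generator,
    arrival_model: ArrivalModel | None = None,
    max_duration_factor: float = 3.0,
    min_sigma_frac: float = 0.25,
    rounding_factor: float = 2.0,
    tempo: float = 0.85,
) -> TrialRecord:
    """Draw the shape once under desirability-mixed segment policies.

    The goods component at each step is the renormalised vertex probability
    over the not-yet-completed vertices on the trial clock; the action
    component comes from per-vertex controllers rebuilt from the current
    state.  Entering the arrival ball of any remaining vertex marks it
    completed (out-of-order entries included — those become transposition
    errors) and triggers re-evaluation conditioned on completion.

    ``tempo`` scales the timetable's segment mean below the realized
    single-segment average: the windows encode the intended drawing pace,
    and keeping them slightly ahead of execution maintains forward pressure
    on the sequence.  Lateness against the schedule then accumulates
    linearly while window widths grow only as sqrt(j) — partially
    re-synchronised at each completion — which is what concentrates
    corner-rounding and transposition errors on the middle segments.
    """
    waypoints = shape.waypoints()
    n_seg = shape.n_segments
    dyn = config.dynamics
    eps = config.arrival_radius_frac * shape.mean_segment_length()
    # completion (conditioning) tolerates a rounded corner; the strict eps
    # ball is what the post-hoc error classifier checks
    eps_complete = rounding_factor * eps

    if arrival_model is None:
        seg_goal = GoalSpec(position=waypoints[1], label="v1")
        ctrl = _segment_controller(dyn, waypoints[0], seg_goal,
                                   horizon_floor=config.horizon_floor)
        fitted = estimate_arrival_model(
            ctrl, n_reps=100, rng=np.random.default_rng(rng.integers(2**31)),
            start=EffectorState(waypoints[0], np.zeros(2), 0),
            arrival_radius=eps_complete, min_sigma_frac=min_sigma_frac,
        )
        arrival_model = ArrivalModel(
            mu_tau=tempo * fitted.mu_tau, sigma_tau=fitted.sigma_tau
        )

    mu_steps = arrival_model.mu_tau / dyn.dt
    max_steps = int(np.ceil(max_duration_factor * n_seg * mu_steps))

    A, B = dyn.system_matrices()
    sd = dyn.process_noise_sd
    x = np.concatenate([waypoints[0], [0.0, 0.0]])
    states = [EffectorState(x[:2].copy(), x[2:].copy(), 0)]
    weight_rows: list[np.ndarray] = []
    controls: list[np.ndarray] = []

    completed = 0  # sequence position of the last vertex reached
    clock = 0.0  # seconds since the last completion event
    visit_order: list[int] = []
    reached = np.zeros(n_seg + 1, dtype=bool)
    reached[0] = True
    # a vertex counts as reached only when entered from outside its arrival
    # ball (the closing vertex of a closed shape starts coincident with the pen)
    was_outside = np.array(
        [np.linalg.norm(x[:2] - waypoints[j]) > eps_complete for j in range(n_seg + 1)]
    )
    timed_out = True
    steps_since_replan = 0
    controllers: list[Controller] = []
    active: list[int] = []
    weights: DesirabilityWeights | None = None

    for step in range(max_steps):
        if weights is None or steps_since_replan >= config.replan_interval:
            # a vertex the pen is still standing on (the closing vertex at
            # trial start) is not a goal yet: it would capture the sharp
            # action softmax with its zero cost
            active = [
                j for j in range(1, n_seg + 1) if not reached[j] and was_outside[j]
            ]
            # slack-free horizons during execution: the shrinking
            # time-to-contact gives the terminal approach its urgency
            controllers = [
                _segment_controller(dyn, x[:2], GoalSpec(position=waypoints[j],
                                                         label=f"v{j}"),
                                    slack=1.0, horizon_floor=config.horizon_floor)
                for j in active
            ]
            state0 = EffectorState(x[:2], x[2:], 0)
            costs = np.array([cost_to_go(c, state0) for c in controllers])
            goods = _origin_anchored_goods(active, reached, clock, arrival_model)
            if len(active) == 1:
                weights = DesirabilityWeights(np.ones(1), np.ones(1), np.ones(1))
            else:
                lam = config.lambda_rule(costs)
                act = action_component(costs, lam)
                weights = combine(act, goods, config.noise, rng)
            steps_since_replan = 0

        u = mixed_action(controllers, weights, EffectorState(x[:2], x[2:], 0))
        controls.append(u)
        row = np.zeros(n_seg)
        for wj, j in zip(weights.weights, active):
            row[j - 1] = wj
        weight_rows.append(row)

        noise_u = rng.normal(0.0, sd, size=2) if sd > 0 else np.zeros(2)
        x = A @ x + B @ (u + noise_u)
        states.append(EffectorState(x[:2].copy(), x[2:].copy(), len(states)))
        clock += dyn.dt
        steps_since_replan += 1

        hit = None
        for j in range(1, n_seg + 1):
            inside = np.linalg.norm(x[:2] - waypoints[j]) <= eps_complete
            if not reached[j] and inside and was_outside[j] and hit is None:
                hit = j
            if not inside:
                was_outside[j] = True
        if hit is not None:
            reached[hit] = True
            visit_order.append(hit)
            completed = max(completed, hit)
            weights = None  # force re-evaluation conditioned on completion
            if all(reached[1:]):
                timed_out = False
                break

    record = TrialRecord(
        states=states,
        weights_per_step=np.array(weight_rows),
        controls=np.array(controls),
        endpoint=states[-1].position.copy(),
        selected_goal=f"v{visit_order[-1]}" if visit_order else "none",
        initial_heading=float(
            np.degrees(np.arctan2(*(states[min(5, len(states) - 1)].position - waypoints[0])[::-1]))
        ),
        error_class="timeout" if timed_out else "none",
        goal_labels=tuple(f"v{j}" for j in range(1, n_seg + 1)),
        visit_order=visit_order,
    )
    if not timed_out:
        record.error_class = classify_copy_error(record, shape)
    return record


def classify_copy_error(
    record: TrialRecord, shape: ShapeSpec, rounding_factor: float = 2.0,
    arrival_radius_frac: float = 0.03,
) -> str:
    """Label a completed copy trial: none, transposition, or corner_rounding.

    Transposition: some vertex was entered out of sequence order (or never
    entered).  Corner rounding: the pen passed a vertex at a distance in
    (eps, rounding_factor * eps] without ever entering the eps ball.
    """
    waypoints = shape.waypoints()
    n_seg = shape.n_segments
    eps = arrival_radius_frac * shape.mean_segment_length()

    order = record.visit_order
    if list(order) != sorted(order) or len(order) < n_seg:
        return "transposition"

    positions = np.array([s.position for s in record.states])
    for j in range(1, n_seg + 1):
        dists = np.linalg.norm(positions - waypoints[j], axis=1)
        closest = dists.min()
        if eps < closest <= rounding_factor * eps:
            return "corner_rounding"
    return "none"


def segment_error_counts(
    records: list[TrialRecord], shape: ShapeSpec, arrival_radius_frac: float = 0.03,
    rounding_factor: float = 2.0,
) -> np.ndarray:
    """Per-segment error counts across trials.

    Segment j is charged with an error when vertex j was reached out of
    order or skipped, or when its corner was rounded.  Used to compare
    error pressure on first/middle/last segments.
    """
    waypoints = shape.waypoints()
    n_seg = shape.n_segments
    eps = arrival_radius_frac * shape.mean_segment_length()
    counts = np.zeros(n_seg)
    for rec in records:
        charged = set()
        unvisited = list(range(1, n_seg + 1))
        for j in rec.visit_order:
            if j not in unvisited:
                continue
            expected = unvisited[0]
            if j != expected:
                # the pen was drawing `expected` when vertex j captured it
                charged.add(expected)
            unvisited.remove(j)
        charged.update(unvisited)  # never completed at all
        positions = np.array([s.position for s in rec.states])
        for j in range(1, n_seg + 1):
            if j in charged:
                continue
            closest = np.linalg.norm(positions - waypoints[j], axis=1).min()
            if eps < closest <= rounding_factor * eps:
                charged.add(j)
        for j in charged:
            counts[j - 1] += 1
    return counts


def chain_arrival_times(
    shape: ShapeSpec,
    dynamics: DynamicsSpec,
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
    arrival_radius_frac: float = 0.03,
    horizon_floor: int = 10,
    reset_velocity_at_vertices: bool = True,
) -> np.ndarray:
    """Cumulative arrival times at each vertex over full chain traversals.

    Each rep draws the whole shape segment by segment under the single-goal
    policies (no competition): segment k's controller engages when segment
    k - 1 completes.  Returns an (n_reps, n_segments) array of arrival
    times from trial start, the empirical counterpart of the composed
    Normal arrival law with mean j * mu and variance j * sigma**2.

    With ``reset_velocity_at_vertices`` (the default) the pen pauses at
    each corner, so segment traversal times are independent and
    identically distributed — the assumption under which the composed
    arrival law holds exactly.
    """
    rng = rng or np.random.default_rng()
    waypoints = shape.waypoints()
    n_seg = shape.n_segments
    eps = arrival_radius_frac * shape.mean_segment_length()

    out = np.empty((n_reps, n_seg))
    for rep in range(n_reps):
        x = np.concatenate([waypoints[0], [0.0, 0.0]])
        elapsed = 0
        for j in range(1, n_seg + 1):
            nominal = default_horizon(dynamics, x[:2], waypoints[j], floor=horizon_floor)
            x, step = _receding_segment_rollout(
                dynamics, x, waypoints[j], eps, rng,
                max_steps=int(np.ceil(3.0 * nominal)), horizon_floor=horizon_floor,
            )
            if step is None:
                raise NonArrivalError(f"rep {rep}: segment {j} never completed")
            elapsed += step
            out[rep, j - 1] = elapsed * dynamics.dt
            if reset_velocity_at_vertices:
                # pen pauses exactly on the corner: segments become iid
                x[:2] = waypoints[j]
                x[2:] = 0.0
    return out
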