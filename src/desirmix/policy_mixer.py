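"""Receding-horizon execution of desirability-weighted policy mixtures.

A trial runs the closed loop: every ``replan_interval`` steps the per-goal
controllers are rebuilt from the current state (fresh time-to-contact
horizons), their costs-to-go are converted to the action component of the
relative desirability, the goods component comes from the goal reward
models, and the mixed control is the desirability-weighted sum of the
per-goal optimal actions.  A cue collapses the weights onto the cued goal;
in saccade mode the weights freeze after a small fraction of the planned
movement (ballistic commitment).  Across trials, goal reward probabilities
can be updated with a delta rule to model trial-history learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from desirmix.desirability import (
    DesirabilityWeights,
    NoiseSpec,
    RewardModel,
    action_component,
    choose_lambda,
    combine,
    goods_component,
    reward_component_binary,
)
from desirmix.optimal_control import (
    ConfigurationError,
    Controller,
    DynamicsSpec,
    EffectorState,
    GoalSpec,
    build_controller,
    cost_to_go,
    default_horizon,
    optimal_action,
)

__all__ = [
    "LambdaRule",
    "TrialConfig",
    "TrialRecord",
    "mixed_action",
    "run_trial",
    "update_goal_probability",
]


@dataclass(frozen=True)
class LambdaRule:
    """How the softmax scale is chosen at each re-planning step."""

    rule: str = "cost_scale"
    kappa: float = 1.0
    fixed_value: float = 1.0

    def __call__(self, costs: np.ndarray) -> float:
        return choose_lambda(
            costs, rule=self.rule, fixed_value=self.fixed_value, kappa=self.kappa
        )


@dataclass(frozen=True)
class TrialConfig:
    """Everything needed to run one decision trial.

    ``cue_step`` is the step at which the true target is revealed (None for
    free-choice trials); ``cued_goal`` names it, or is sampled from the
    goal reward probabilities when left unset.  ``commit_fraction`` applies
    in saccade mode: the fraction of the planned duration after which the
    desirability weights freeze.  ``goods_mode`` selects the goods-related
    component: ``"binary"`` (renormalised reward probabilities, equal
    magnitudes) or ``"gaussian"`` (session-average comparison of stochastic
    magnitudes).
    """

    goals: tuple[GoalSpec, ...]
    dynamics: DynamicsSpec = DynamicsSpec()
    cue_step: int | None = None
    cued_goal: str | None = None
    replan_interval: int = 1
    commit_fraction: float = 0.2
    lambda_rule: LambdaRule = LambdaRule()
    noise: NoiseSpec = NoiseSpec()
    goods_mode: str = "binary"
    n_session_trials: int = 100
    start_position: tuple[float, float] = (0.0, 0.0)
    arrival_radius_frac: float = 0.03
    max_steps_factor: float = 3.0
    horizon_floor: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.goals) < 1:
            raise ConfigurationError("need at least one goal")
        if self.replan_interval < 1:
            raise ConfigurationError("replan_interval must be >= 1")
        if not 0.0 <= self.commit_fraction <= 1.0:
            raise ConfigurationError("commit_fraction must lie in [0, 1]")

    def reward_models(self) -> list[RewardModel]:
        return [
            RewardModel(g.reward_prob, g.reward_mean, g.reward_sd, self.n_session_trials)
            for g in self.goals
        ]


@dataclass
class TrialRecord:
    """Trajectory, per-step weights, and outcome summary of one trial."""

    states: list[EffectorState]
    weights_per_step: np.ndarray  # (n_steps, n_goals)
    controls: np.ndarray  # (n_steps, 2)
    endpoint: np.ndarray
    selected_goal: str
    initial_heading: float  # degrees, atan2 convention
    error_class: str = "none"
    goal_labels: tuple[str, ...] = ()
    visit_order: list[int] = field(default_factory=list)  # used by copy trials

    @property
    def n_steps(self) -> int:
        return len(self.states) - 1


def mixed_action(
    controllers: list[Controller],
    weights: DesirabilityWeights | np.ndarray,
    state: EffectorState,
) -> np.ndarray:
    """Desirability-weighted average of the per-goal optimal actions."""
    w = weights.weights if isinstance(weights, DesirabilityWeights) else np.asarray(weights, float)
    if len(w) != len(controllers):
        raise ValueError(
            f"{len(w)} weights for {len(controllers)} controllers"
        )
    u = np.zeros(2)
    for wj, ctrl in zip(w, controllers):
        if wj == 0.0:
            continue
        t = min(state.t, ctrl.horizon - 1)  # clamp inside the horizon
        clamped = EffectorState(state.position, state.velocity, t)
        u += wj * optimal_action(ctrl, clamped)
    return u


def _fresh_controllers(
    config: TrialConfig, position: np.ndarray
) -> tuple[list[Controller], np.ndarray]:
    """Rebuild per-goal controllers with time-to-contact horizons."""
    controllers, costs = [], []
    state = EffectorState(position[:2], position[2:], 0)
    for goal in config.goals:
        T = default_horizon(config.dynamics, position[:2], goal.position,
                            floor=config.horizon_floor)
        ctrl = build_controller(config.dynamics, goal, T)
        controllers.append(ctrl)
        costs.append(cost_to_go(ctrl, state))
    return controllers, np.asarray(costs)


def _desirability(
    config: TrialConfig,
    costs: np.ndarray,
    goods: np.ndarray,
    rng: np.random.Generator,
) -> DesirabilityWeights:
    if len(costs) == 1:
        one = np.ones(1)
        return DesirabilityWeights(one, one, one)
    lam = config.lambda_rule(costs)
    act = action_component(costs, lam)
    return combine(act, goods, config.noise, rng)


def _goods_vector(config: TrialConfig, rng: np.random.Generator) -> np.ndarray:
    if len(config.goals) == 1:
        return np.array([1.0])
    if config.goods_mode == "binary":
        return reward_component_binary([g.reward_prob for g in config.goals])
    if config.goods_mode == "gaussian":
        return goods_component(config.reward_models(), method="cumnorm", rng=rng)
    raise ConfigurationError(f"unknown goods_mode {config.goods_mode!r}")


def _initial_heading(
    states: list[EffectorState], start: np.ndarray, threshold: float
) -> float:
    """Direction of travel once the effector has cleared ``threshold``."""
    for s in states[1:]:
        d = s.position - start
        if np.linalg.norm(d) >= threshold:
            return float(np.degrees(np.arctan2(d[1], d[0])))
    d = states[-1].position - start
    return float(np.degrees(np.arctan2(d[1], d[0])))


def run_trial(config: TrialConfig, rng: np.random.Generator) -> TrialRecord:
    """Run one receding-horizon trial and classify its outcome.

    The loop rebuilds controllers and re-evaluates the relative desirability
    every ``replan_interval`` steps; at the cue step the weights collapse
    onto the cued goal; saccade trials freeze their weights after
    ``commit_fraction`` of the planned duration.  The trial ends on arrival
    within the arrival radius of any goal, or at the step budget.
    """
    n_goals = len(config.goals)
    start = np.asarray(config.start_position, dtype=float)
    labels = tuple(g.label for g in config.goals)

    dists = [np.linalg.norm(g.position - start) for g in config.goals]
    mean_dist = float(np.mean(dists))
    eps = config.arrival_radius_frac * mean_dist
    T_plan = max(
        default_horizon(config.dynamics, start, g.position, floor=config.horizon_floor)
        for g in config.goals
    )
    max_steps = int(np.ceil(config.max_steps_factor * T_plan))
    commit_step = (
        int(np.ceil(config.commit_fraction * T_plan))
        if config.dynamics.mode == "saccade"
        else None
    )

    cued_idx: int | None = None
    if config.cue_step is not None:
        if config.cued_goal is not None:
            cued_idx = labels.index(config.cued_goal)
        else:
            probs = np.array([g.reward_prob for g in config.goals], float)
            probs = probs / probs.sum()
            cued_idx = int(rng.choice(n_goals, p=probs))

    goods = _goods_vector(config, rng)
    x = np.concatenate([start, [0.0, 0.0]])
    A, B = config.dynamics.system_matrices()
    sd = config.dynamics.process_noise_sd

    states = [EffectorState(x[:2].copy(), x[2:].copy(), 0)]
    weight_rows: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    controllers: list[Controller] = []
    weights: DesirabilityWeights | None = None
    frozen = False
    steps_since_replan = 0

    for step in range(max_steps):
        cue_now = config.cue_step is not None and step >= config.cue_step
        if step == 0 or steps_since_replan >= config.replan_interval:
            controllers, costs = _fresh_controllers(config, x)
            if not frozen and not cue_now:
                weights = _desirability(config, costs, goods, rng)
            steps_since_replan = 0
        if cue_now:
            one_hot = np.zeros(n_goals)
            one_hot[cued_idx] = 1.0
            weights = DesirabilityWeights(one_hot, one_hot, one_hot)
        if commit_step is not None and step >= commit_step:
            frozen = True

        state = EffectorState(x[:2], x[2:], 0)
        u = mixed_action(controllers, weights, state)
        controls.append(u)
        weight_rows.append(weights.weights.copy())

        noise_u = rng.normal(0.0, sd, size=2) if sd > 0 else np.zeros(2)
        x = A @ x + B @ (u + noise_u)
        states.append(EffectorState(x[:2].copy(), x[2:].copy(), len(states)))
        steps_since_replan += 1

        goal_dists = [np.linalg.norm(x[:2] - g.position) for g in config.goals]
        nearest = int(np.argmin(goal_dists))
        if goal_dists[nearest] <= eps and (cued_idx is None or nearest == cued_idx):
            break

    endpoint = states[-1].position
    goal_dists = [np.linalg.norm(endpoint - g.position) for g in config.goals]
    nearest = int(np.argmin(goal_dists))
    selected = labels[nearest] if goal_dists[nearest] <= 2 * eps else "none"
    heading = _initial_heading(states, start, 0.1 * mean_dist)

    if selected == "none":
        error_class = "averaged"
    elif cued_idx is not None and config.cue_step is not None and config.cue_step > 0:
        goal_dir = config.goals[nearest].position - start
        goal_angle = np.degrees(np.arctan2(goal_dir[1], goal_dir[0]))
        dev = abs((heading - goal_angle + 180) % 360 - 180)
        error_class = "corrected" if dev > 5.0 else "direct"
    else:
        error_class = "direct"

    return TrialRecord(
        states=states,
        weights_per_step=np.array(weight_rows),
        controls=np.array(controls),
        endpoint=endpoint.copy(),
        selected_goal=selected,
        initial_heading=heading,
        error_class=error_class,
        goal_labels=labels,
    )


def update_goal_probability(
    probs: np.ndarray, cued: int, alpha: float
) -> np.ndarray:
    """Delta-rule update of goal probabilities from one cued trial.

    The cued goal moves toward certainty, ``p <- p + alpha (1 - p)``; the
    remaining goals are rescaled so the vector still sums to one.
    """
    probs = np.asarray(probs, dtype=float)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"learning rate must lie in [0, 1], got {alpha}")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    if not 0 <= cued < len(probs):
        raise ValueError(f"cued index {cued} out of range")
    new = probs.copy()
    old_p = probs[cued]
    new[cued] = old_p + alpha * (1.0 - old_p)
    rest = 1.0 - old_p
    if rest > 0:
        new_rest = 1.0 - new[cued]
        for i in range(len(probs)):
            if i != cued:
                new[i] = probs[i] * new_rest / rest
    return new
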