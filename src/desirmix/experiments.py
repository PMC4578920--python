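"""Scenario runners: desirability maps, saccade sweeps, and hemifield biases.

These functions reproduce the computational content of the framework's
standard decision scenarios: visualising the relative-desirability field of
two competing policies on a circle (reaches) or ellipse (saccades) of probe
states, measuring how often saccades to target pairs land between the
targets as a function of angular separation (the global effect), and
quantifying the heading bias induced by unequal target counts across
hemifields.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from desirmix.desirability import (
    NoiseSpec,
    action_component,
    reward_component_binary,
)
from desirmix.optimal_control import (
    ConfigurationError,
    DynamicsSpec,
    EffectorState,
    GoalSpec,
    build_controller,
    default_horizon,
    simulate_trajectory,
)
from desirmix.policy_mixer import LambdaRule, TrialConfig, run_trial

__all__ = [
    "MapSlice",
    "desirability_map",
    "classify_averaging",
    "separation_sweep",
    "hemifield_bias",
    "saccade_pair_config",
    "reach_pair_config",
]

# Saccades evolve on a millisecond grid; defaults chosen so a 10-unit
# saccade spans ~50 steps, leaving a usable pre-commitment window.
SACCADE_DT = 0.001
SACCADE_PROCESS_NOISE = 300.0
SACCADE_ESTIMATION_NOISE = 0.05
REACH_PROCESS_NOISE = 10.0
REACH_ESTIMATION_NOISE = 0.02


@dataclass(frozen=True)
class MapSlice:
    """Desirability of one goal probed on a slice through state space."""

    points: np.ndarray  # (n, 4): position and velocity per probe
    values: np.ndarray  # (n,) desirability of the designated goal
    geometry: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if len(self.points) != len(self.values):
            raise ConfigurationError("one value per probe point required")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ConfigurationError("desirability values must lie in [0, 1]")


def reach_pair_config(
    separation: float = 10.0,
    distance: float = 10.0,
    reward_probs: tuple[float, float] = (0.5, 0.5),
    **overrides,
) -> TrialConfig:
    """Two reach targets left/right of the midline at equal distance."""
    half = separation / 2.0
    y = np.sqrt(max(distance**2 - half**2, 1e-9))
    goals = (
        GoalSpec(position=[-half, y], reward_prob=reward_probs[0], label="L"),
        GoalSpec(position=[half, y], reward_prob=reward_probs[1], label="R"),
    )
    defaults = dict(
        goals=goals,
        dynamics=DynamicsSpec(process_noise_sd=REACH_PROCESS_NOISE),
        noise=NoiseSpec(noise_sd=REACH_ESTIMATION_NOISE),
        lambda_rule=LambdaRule(kappa=0.5),
    )
    defaults.update(overrides)
    return TrialConfig(**defaults)


def saccade_pair_config(
    separation_deg: float,
    eccentricity: float = 10.0,
    commit_fraction: float = 0.2,
    **overrides,
) -> TrialConfig:
    """Two equally rewarded saccade targets separated by a visual angle.

    Targets sit at the given eccentricity, symmetric about the vertical
    meridian; the separation is the angle subtended at the fixation point.
    """
    a_right = np.radians(90.0 - separation_deg / 2.0)
    a_left = np.radians(90.0 + separation_deg / 2.0)
    goals = (
        GoalSpec(
            position=[eccentricity * np.cos(a_left), eccentricity * np.sin(a_left)],
            reward_prob=0.5, label="L",
        ),
        GoalSpec(
            position=[eccentricity * np.cos(a_right), eccentricity * np.sin(a_right)],
            reward_prob=0.5, label="R",
        ),
    )
    defaults = dict(
        goals=goals,
        dynamics=DynamicsSpec(
            dt=SACCADE_DT, mode="saccade", process_noise_sd=SACCADE_PROCESS_NOISE
        ),
        noise=NoiseSpec(noise_sd=SACCADE_ESTIMATION_NOISE),
        commit_fraction=commit_fraction,
        lambda_rule=LambdaRule(kappa=1.0),
    )
    defaults.update(overrides)
    return TrialConfig(**defaults)


def _optimal_speed_at_fraction(
    config: TrialConfig, goal: GoalSpec, fraction: float
) -> float:
    """Speed of the noiseless single-goal optimal movement at a path fraction."""
    dyn = replace(config.dynamics, process_noise_sd=0.0)
    T = default_horizon(dyn, config.start_position, goal.position,
                        floor=config.horizon_floor)
    ctrl = build_controller(dyn, goal, T)
    states, _ = simulate_trajectory(
        ctrl, EffectorState(np.asarray(config.start_position, float), np.zeros(2)),
        np.random.default_rng(0),
    )
    start = np.asarray(config.start_position, float)
    total = np.linalg.norm(goal.position - start)
    for s in states:
        if np.linalg.norm(s.position - start) >= fraction * total:
            return float(np.linalg.norm(s.velocity))
    return float(np.linalg.norm(states[-1].velocity))


def desirability_map(
    config: TrialConfig,
    target_label: str,
    geometry: str = "circle",
    n_points: int = 100,
    n_samples: int = 100,
    rng: np.random.Generator | None = None,
    radius_fraction: float = 0.85,
) -> MapSlice:
    """Desirability of one goal over a slice of probe states.

    ``circle`` places probes on a circle of ``radius_fraction`` of the
    start-to-midpoint distance, with radially outward velocities whose
    magnitude matches the optimal single-goal reach speed at that fraction
    of completion.  ``ellipse`` places probes at rest on an ellipse centred
    between the targets (minor axis twice the start-to-centre distance,
    major axis twice the minor, major axis perpendicular to the
    start-to-centre line).  At each probe the per-goal action cost is the
    average realized cost of ``n_samples`` noisy rollouts, converted to the
    action component, combined with the goods component, and the designated
    goal's weight returned.
    """
    if len(config.goals) < 2:
        raise ConfigurationError("a desirability map needs at least 2 goals")
    if n_points < 8:
        raise ConfigurationError("need at least 8 probe points")
    rng = rng or np.random.default_rng()
    labels = [g.label for g in config.goals]
    target_idx = labels.index(target_label)

    start = np.asarray(config.start_position, float)
    midpoint = np.mean([g.position for g in config.goals], axis=0)
    to_mid = midpoint - start
    mid_dist = float(np.linalg.norm(to_mid))

    angles = 2 * np.pi * np.arange(n_points) / n_points
    if geometry == "circle":
        radius = radius_fraction * mid_dist
        speed = _optimal_speed_at_fraction(
            config, config.goals[target_idx], radius_fraction
        )
        directions = np.column_stack([np.cos(angles), np.sin(angles)])
        positions = start + radius * directions
        velocities = speed * directions
    elif geometry == "ellipse":
        minor = 2.0 * mid_dist
        major = 2.0 * minor
        u_mid = to_mid / mid_dist  # minor axis along start->centre
        u_perp = np.array([-u_mid[1], u_mid[0]])  # major axis across it
        offsets = (
            np.outer(np.cos(angles) * (major / 2.0), u_perp)
            + np.outer(np.sin(angles) * (minor / 2.0), u_mid)
        )
        positions = midpoint + offsets
        velocities = np.zeros_like(positions)
    else:
        raise ConfigurationError(f"unknown geometry {geometry!r}")

    goods = reward_component_binary([g.reward_prob for g in config.goals])
    values = np.empty(n_points)
    points = np.hstack([positions, velocities])
    for i in range(n_points):
        state = EffectorState(positions[i], velocities[i], 0)
        costs = np.empty(len(config.goals))
        for k, goal in enumerate(config.goals):
            T = default_horizon(config.dynamics, positions[i], goal.position,
                                floor=config.horizon_floor)
            ctrl = build_controller(config.dynamics, goal, T)
            realized = [
                simulate_trajectory(ctrl, state, rng)[1] for _ in range(n_samples)
            ]
            costs[k] = np.mean(realized)
        lam = config.lambda_rule(costs)
        act = action_component(costs, lam)
        combined = act * goods
        values[i] = combined[target_idx] / combined.sum()
    return MapSlice(points=points, values=values, geometry=geometry)


def classify_averaging(endpoint: np.ndarray, goals: tuple[GoalSpec, GoalSpec],
                       start: np.ndarray | None = None) -> bool:
    """True iff the endpoint lies in the central third of the target sector.

    The sector is the angular interval between the two target directions as
    seen from the start position; endpoints on the central-third boundary
    count as not averaging.
    """
    if len(goals) != 2:
        raise ConfigurationError("averaging is defined for exactly 2 goals")
    start = np.zeros(2) if start is None else np.asarray(start, float)
    end = np.asarray(endpoint, float) - start
    a = [
        np.arctan2(*(g.position - start)[::-1]) for g in goals
    ]
    lo, hi = min(a), max(a)
    third = (hi - lo) / 3.0
    ang = float(np.arctan2(end[1], end[0]))
    return bool(lo + third < ang < hi - third)


def separation_sweep(
    angles_deg: list[float],
    n_trials: int = 200,
    rng: np.random.Generator | None = None,
    eccentricity: float = 10.0,
    **config_overrides,
) -> dict[float, tuple[float, float]]:
    """Percentage of averaging saccades per target separation angle.

    Returns ``{angle: (percent_averaging, binomial_se_percent)}``.
    """
    if n_trials < 50:
        raise ConfigurationError("need at least 50 trials per angle")
    for a in angles_deg:
        if not 0.0 < a < 180.0:
            raise ConfigurationError(f"separation {a} outside (0, 180)")
    rng = rng or np.random.default_rng()
    out: dict[float, tuple[float, float]] = {}
    for angle in angles_deg:
        config = saccade_pair_config(angle, eccentricity, **config_overrides)
        n_avg = 0
        for _ in range(n_trials):
            trial_rng = np.random.default_rng(rng.integers(2**31))
            rec = run_trial(config, trial_rng)
            if classify_averaging(rec.endpoint, config.goals,
                                  np.asarray(config.start_position, float)):
                n_avg += 1
        p = n_avg / n_trials
        se = np.sqrt(p * (1 - p) / n_trials)
        out[angle] = (100.0 * p, 100.0 * se)
    return out


def hemifield_bias(
    n_left: int,
    n_right: int,
    config: TrialConfig | None = None,
    rng: np.random.Generator | None = None,
    n_trials: int = 100,
    eccentricity: float = 10.0,
    span_deg: float = 80.0,
) -> float:
    """Mean signed initial heading (degrees) with unequal hemifield targets.

    Targets are spread at equal eccentricity over a symmetric angular span
    around straight ahead (90 degrees), ``n_left`` in the left hemifield
    and ``n_right`` in the right.  The returned value is the mean initial
    heading relative to straight ahead: positive = leftward bias.
    """
    if n_left + n_right < 2:
        raise ConfigurationError("need at least 2 targets")
    rng = rng or np.random.default_rng()

    angles = []
    for i in range(n_left):
        angles.append(90.0 + span_deg / 2.0 * (i + 1) / n_left)
    for i in range(n_right):
        angles.append(90.0 - span_deg / 2.0 * (i + 1) / n_right)
    goals = tuple(
        GoalSpec(
            position=[
                eccentricity * np.cos(np.radians(a)),
                eccentricity * np.sin(np.radians(a)),
            ],
            reward_prob=1.0 / (n_left + n_right),
            label=f"g{i}",
        )
        for i, a in enumerate(angles)
    )
    if config is None:
        config = TrialConfig(
            goals=goals,
            dynamics=DynamicsSpec(process_noise_sd=REACH_PROCESS_NOISE),
            noise=NoiseSpec(noise_sd=REACH_ESTIMATION_NOISE),
        )
    else:
        config = replace(config, goals=goals)

    headings = []
    for _ in range(n_trials):
        trial_rng = np.random.default_rng(rng.integers(2**31))
        rec = run_trial(config, trial_rng)
        headings.append(rec.initial_heading - 90.0)
    return float(np.mean(headings))
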