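"""Finite-horizon stochastic optimal controllers for a planar point-mass effector.

Each goal (reach target, saccade target, or shape vertex) gets its own
controller: a discrete-time linear-quadratic regulator over the state
``x = (px, py, vx, vy)`` with viscous damping and additive Gaussian motor
noise on the control channels.  The controller exposes the optimal policy
``u = pi(x)`` and the quadratic cost-to-go ``V(x)`` — the expected effort
accumulated from the current state plus the terminal accuracy penalty —
which is the action-cost half of the relative-desirability computation.

Because the goal enters only through a coordinate shift (the goal state has
zero velocity and is a fixed point of the drift), the Riccati recursion is
independent of the goal position and depends only on (dynamics, weights,
steps-to-go).  Solutions are memoised by steps-to-go so that receding-horizon
re-planning, which rebuilds controllers every step, costs almost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "OutOfHorizonError",
    "DynamicsSpec",
    "EffectorState",
    "GoalSpec",
    "Controller",
    "build_controller",
    "optimal_action",
    "cost_to_go",
    "simulate_trajectory",
    "default_horizon",
]


class ConfigurationError(ValueError):
    """Raised for invalid dynamics, weights, or horizon settings."""


class OutOfHorizonError(IndexError):
    """Raised when a policy is queried at or past its planning horizon."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DynamicsSpec:
    """Discrete-time point-mass effector dynamics.

    Parameters
    ----------
    dt:
        Integration time step in seconds.
    mass:
        Effector mass (arbitrary units).
    damping:
        Viscous coefficient; velocity decays by ``1 - damping*dt/mass``
        per step.
    process_noise_sd:
        Standard deviation of additive Gaussian motor noise injected on
        each control dimension (same units as the control signal).
    mode:
        ``"reach"`` (hand) or ``"saccade"`` (eye).  Saccades use a faster
        reference speed and, by default, a terminal zero-velocity penalty.
    """

    dt: float = 0.01
    mass: float = 1.0
    damping: float = 10.0
    process_noise_sd: float = 0.0
    mode: Literal["reach", "saccade"] = "reach"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.mass <= 0:
            raise ConfigurationError(f"mass must be positive, got {self.mass}")
        if self.damping < 0:
            raise ConfigurationError(f"damping must be >= 0, got {self.damping}")
        if self.process_noise_sd < 0:
            raise ConfigurationError(
                f"process_noise_sd must be >= 0, got {self.process_noise_sd}"
            )
        if self.mode not in ("reach", "saccade"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")

    @property
    def reference_speed(self) -> float:
        """Nominal movement speed used to convert distance into a horizon."""
        return 200.0 if self.mode == "saccade" else 25.0

    def system_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the (A, B) pair of the discrete-time linear system."""
        a = 1.0 - self.damping * self.dt / self.mass
        A = np.array(
            [
                [1.0, 0.0, self.dt, 0.0],
                [0.0, 1.0, 0.0, self.dt],
                [0.0, 0.0, a, 0.0],
                [0.0, 0.0, 0.0, a],
            ]
        )
        B = np.array(
            [
                [0.0, 0.0],
                [0.0, 0.0],
                [self.dt / self.mass, 0.0],
                [0.0, self.dt / self.mass],
            ]
        )
        return A, B


@dataclass(frozen=True)
class EffectorState:
    """Effector position/velocity at an integer step index."""

    position: np.ndarray
    velocity: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))
        if self.position.shape != (2,) or self.velocity.shape != (2,):
            raise ConfigurationError("position and velocity must be 2-vectors")
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.velocity))):
            raise ConfigurationError("state components must be finite")
        if self.t < 0:
            raise ConfigurationError(f"step index must be >= 0, got {self.t}")

    def vector(self) -> np.ndarray:
        return np.concatenate([self.position, self.velocity])


@dataclass(frozen=True)
class GoalSpec:
    """A target with its reward model: the unit of competition.

    ``reward_prob`` is the probability p that the goal pays out at all;
    when it does, the magnitude is Normal(reward_mean, reward_sd**2).
    A fixed certain reward is ``reward_prob=1, reward_sd=0``.
    """

    position: np.ndarray
    reward_prob: float = 1.0
    reward_mean: float = 1.0
    reward_sd: float = 0.0
    label: str = "goal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (2,):
            raise ConfigurationError("goal position must be a 2-vector")
        if not 0.0 <= self.reward_prob <= 1.0:
            raise ConfigurationError(
                f"reward_prob must lie in [0, 1], got {self.reward_prob}"
            )
        if self.reward_mean < 0:
            raise ConfigurationError(f"reward_mean must be >= 0, got {self.reward_mean}")
        if self.reward_sd < 0:
            raise ConfigurationError(f"reward_sd must be >= 0, got {self.reward_sd}")

    def state_vector(self) -> np.ndarray:
        """Goal expressed as a full state: at the target, at rest."""
        return np.concatenate([self.position, [0.0, 0.0]])


@dataclass
class Controller:
    """A per-goal finite-horizon policy with its quadratic cost-to-go.

    ``gains[t]`` is the feedback matrix applied to the goal-relative state
    at step ``t`` (``u = -K_t (x - x_goal)``).  ``value_quadratic[t]`` is a
    ``(P, b, c)`` triple so that the cost-to-go from goal-relative state z
    at step t is ``z' P z + b' z + c``; the linear term is identically zero
    for this problem and is kept for interface generality.  There are
    ``horizon + 1`` value triples (steps 0..horizon inclusive); the last is
    the pure terminal accuracy penalty.
    """

    goal: GoalSpec
    dynamics: DynamicsSpec
    horizon: int
    gains: np.ndarray  # (horizon, 2, 4)
    value_quadratic: list[tuple[np.ndarray, np.ndarray, float]]
    accuracy_weight: np.ndarray
    effort_weight: np.ndarray

    def relative_state(self, state: EffectorState) -> np.ndarray:
        return state.vector() - self.goal.state_vector()


# ---------------------------------------------------------------------------
# Riccati recursion, memoised by steps-to-go
# ---------------------------------------------------------------------------


class _RiccatiTable:
    """Backward dynamic-programming solution indexed by steps-to-go.

    For time-invariant (A, B, Q_T, R) the optimal gain with s steps to go
    does not depend on the total horizon, so one growing table serves every
    controller sharing the same dynamics and weights.
    """

    def __init__(self, A: np.ndarray, B: np.ndarray, QT: np.ndarray, R: np.ndarray):
        self.A, self.B, self.QT, self.R = A, B, QT, R
        self.P: list[np.ndarray] = [QT.copy()]  # P[s], s = steps to go
        self.K: list[np.ndarray] = []  # K[s] valid for s >= 1 (K[0] unused pad)
        self.trace_bb: list[float] = [0.0]  # sum_{k<s} tr(P[k] B B')
        self._BBt = B @ B.T

    def extend(self, s_max: int) -> None:
        A, B, R = self.A, self.B, self.R
        while len(self.P) <= s_max:
            Pn = self.P[-1]
            G = R + B.T @ Pn @ B
            K = np.linalg.solve(G, B.T @ Pn @ A)
            P = A.T @ Pn @ (A - B @ K)
            P = 0.5 * (P + P.T)
            if len(self.K) == 0:
                self.K.append(np.zeros_like(K))  # pad so K[s] aligns with P[s]
            self.K.append(K)
            self.P.append(P)
            self.trace_bb.append(self.trace_bb[-1] + float(np.trace(Pn @ self._BBt)))


_riccati_cache: dict[bytes, _RiccatiTable] = {}


def _riccati_table(
    dynamics: DynamicsSpec, QT: np.ndarray, R: np.ndarray
) -> _RiccatiTable:
    A, B = dynamics.system_matrices()
    key = A.tobytes() + B.tobytes() + QT.tobytes() + R.tobytes()
    table = _riccati_cache.get(key)
    if table is None:
        table = _RiccatiTable(A, B, QT, R)
        _riccati_cache[key] = table
    return table


# Default accuracy/effort trade-off.  With the default dynamics and a
# horizon from `default_horizon`, these ratios bring noiseless movements
# within well under 1% of the start-to-target distance.  Saccades are much
# faster than reaches, so their effort weight is smaller, and they carry a
# terminal velocity penalty so the eye lands at rest.
DEFAULT_ACCURACY = 1.0
DEFAULT_EFFORT_REACH = 1e-7
DEFAULT_EFFORT_SACCADE = 1e-10
SACCADE_VELOCITY_WEIGHT = 1e-3


def _default_weights(dynamics: DynamicsSpec) -> tuple[np.ndarray, np.ndarray]:
    QT = np.zeros((4, 4))
    QT[0, 0] = QT[1, 1] = DEFAULT_ACCURACY
    if dynamics.mode == "saccade":
        # saccades terminate at rest: penalize residual velocity too
        QT[2, 2] = QT[3, 3] = SACCADE_VELOCITY_WEIGHT
        R = DEFAULT_EFFORT_SACCADE * np.eye(2)
    else:
        R = DEFAULT_EFFORT_REACH * np.eye(2)
    return QT, R


def default_horizon(
    dynamics: DynamicsSpec,
    start_position: Sequence[float],
    goal_position: Sequence[float],
    floor: int = 10,
) -> int:
    """Planning horizon as time-to-contact: distance over reference speed."""
    dist = float(np.linalg.norm(np.asarray(goal_position) - np.asarray(start_position)))
    steps = int(np.ceil(dist / dynamics.reference_speed / dynamics.dt))
    return max(floor, steps)


def build_controller(
    dynamics: DynamicsSpec,
    goal: GoalSpec,
    horizon: int,
    accuracy_weight: np.ndarray | None = None,
    effort_weight: np.ndarray | None = None,
) -> Controller:
    """Solve the finite-horizon LQ problem for one goal.

    The cost is the terminal accuracy penalty ``(x_T - x_goal)' Q_T
    (x_T - x_goal)`` plus the accumulated effort ``sum_t u_t' R u_t``.
    Backward dynamic programming gives the exact gain schedule and the
    quadratic cost-to-go at every step; additive motor noise contributes a
    state-independent constant at each step.
    """
    if horizon < 1:
        raise ConfigurationError(f"horizon must be >= 1, got {horizon}")
    QT_default, R_default = _default_weights(dynamics)
    QT = QT_default if accuracy_weight is None else np.asarray(accuracy_weight, float)
    R = R_default if effort_weight is None else np.asarray(effort_weight, float)
    if QT.shape != (4, 4) or R.shape != (2, 2):
        raise ConfigurationError("accuracy_weight must be 4x4 and effort_weight 2x2")
    if not np.allclose(QT, QT.T) or np.any(np.linalg.eigvalsh(QT) < -1e-12):
        raise ConfigurationError("accuracy_weight must be symmetric PSD")
    if not np.allclose(R, R.T) or np.any(np.linalg.eigvalsh(R) <= 0):
        raise ConfigurationError("effort_weight must be symmetric positive definite")

    table = _riccati_table(dynamics, QT, R)
    table.extend(horizon)

    sigma2 = dynamics.process_noise_sd**2
    gains = np.stack([table.K[horizon - t] for t in range(horizon)])
    zero = np.zeros(4)
    value = [
        (table.P[horizon - t], zero, sigma2 * table.trace_bb[horizon - t])
        for t in range(horizon + 1)
    ]
    return Controller(
        goal=goal,
        dynamics=dynamics,
        horizon=horizon,
        gains=gains,
        value_quadratic=value,
        accuracy_weight=QT,
        effort_weight=R,
    )


def optimal_action(controller: Controller, state: EffectorState) -> np.ndarray:
    """The policy's control at ``state``: affine feedback on the goal error."""
    if state.t >= controller.horizon:
        raise OutOfHorizonError(
            f"step {state.t} is at or past horizon {controller.horizon}"
        )
    z = controller.relative_state(state)
    return -controller.gains[state.t] @ z


def cost_to_go(controller: Controller, state: EffectorState) -> float:
    """Expected accumulated effort + terminal accuracy cost from ``state``."""
    if state.t > controller.horizon:
        raise OutOfHorizonError(
            f"step {state.t} is past horizon {controller.horizon}"
        )
    P, b, c = controller.value_quadratic[state.t]
    z = controller.relative_state(state)
    return float(z @ P @ z + b @ z + c)


def simulate_trajectory(
    controller: Controller,
    start: EffectorState,
    rng: np.random.Generator,
) -> tuple[list[EffectorState], float]:
    """Roll out the closed loop with additive motor noise.

    Returns the state sequence (horizon + 1 states including the start) and
    the realized cost (accumulated effort plus the terminal accuracy
    penalty).  Identical generators produce bitwise-identical rollouts.
    """
    if start.t != 0:
        raise ConfigurationError("trajectory simulation must start at step 0")
    A, B = controller.dynamics.system_matrices()
    sd = controller.dynamics.process_noise_sd
    R = controller.effort_weight
    x = start.vector()
    states = [start]
    realized = 0.0
    for t in range(controller.horizon):
        u = -controller.gains[t] @ (x - controller.goal.state_vector())
        realized += float(u @ R @ u)
        noise = rng.normal(0.0, sd, size=2) if sd > 0 else np.zeros(2)
        x = A @ x + B @ (u + noise)
        states.append(EffectorState(position=x[:2].copy(), velocity=x[2:].copy(), t=t + 1))
    zT = x - controller.goal.state_vector()
    realized += float(zT @ controller.accuracy_weight @ zT)
    return states, realized
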