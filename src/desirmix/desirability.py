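"""Relative desirability: action costs and goods values in one probability currency.

Each candidate goal j carries two probabilities evaluated at the current
state:

* the **action component** — the probability that following goal j's policy
  incurs the lowest action cost among the alternatives, approximated by a
  softmax over the per-goal costs-to-go with inverse-temperature scale
  ``lam``;
* the **goods component** — the probability that goal j pays the highest
  reward, from either bare reward probabilities (fixed equal magnitudes) or
  a session-average comparison of stochastic reward magnitudes.

Their product, renormalised across goals, is the relative desirability: the
probability of getting the highest pay-off with the least effort by
committing to that goal now.  Small estimation noise on the two components
resolves the 0/0 indeterminacy that arises when one option strictly
dominates on reward and the other on effort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, log_softmax

__all__ = [
    "RewardModel",
    "NoiseSpec",
    "DesirabilityWeights",
    "action_component",
    "reward_component_binary",
    "reward_component_gaussian",
    "combine",
    "choose_lambda",
    "goods_component",
]


@dataclass(frozen=True)
class RewardModel:
    """Stochastic reward attached to a goal.

    The reward on one trial is 0 with probability ``1 - reward_prob`` and
    Normal(reward_mean, reward_sd**2) otherwise.  ``n_trials`` is the
    session length over which average rewards are compared.
    """

    reward_prob: float
    reward_mean: float
    reward_sd: float
    n_trials: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.reward_prob <= 1.0:
            raise ValueError(f"reward_prob must be in [0, 1], got {self.reward_prob}")
        if self.reward_sd < 0:
            raise ValueError(f"reward_sd must be >= 0, got {self.reward_sd}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")

    def session_mean_params(self) -> tuple[float, float]:
        """Mean and variance of the session-average reward under the model.

        The session average is treated as Normal with mean ``p * mu`` and
        variance ``sigma**2 / (p * N)`` — the large-session law used
        throughout the framework.
        """
        if self.reward_prob <= 0:
            raise ValueError("session-average law undefined for reward_prob = 0")
        mean = self.reward_prob * self.reward_mean
        var = self.reward_sd**2 / (self.reward_prob * self.n_trials)
        return mean, var


@dataclass(frozen=True)
class NoiseSpec:
    """Estimation noise on each desirability component.

    ``noise_sd`` is the s.d. of independent zero-mean Gaussian perturbations
    added to every component value; ``floor`` is a small positive clip that
    keeps perturbed components strictly positive, so the normalising sum can
    never vanish.
    """

    noise_sd: float = 0.0
    floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 < self.floor < 1.0:
            raise ValueError(f"floor must lie in (0, 1), got {self.floor}")


@dataclass(frozen=True)
class DesirabilityWeights:
    """Normalized per-goal weights with their two components."""

    weights: np.ndarray
    action_component: np.ndarray
    goods_component: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "action_component", np.asarray(self.action_component, float))
        object.__setattr__(self, "goods_component", np.asarray(self.goods_component, float))
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.weights)


def action_component(costs: np.ndarray, lam: float) -> np.ndarray:
    """Probability that each goal's policy is cheapest: softmax of -cost/lam.

    Computed as ``exp(-V_j/lam) / sum_i exp(-V_i/lam)`` in max-shifted form,
    so it is exactly invariant to adding a constant to every cost and safe
    for large cost magnitudes.
    """
    costs = np.asarray(costs, dtype=float)
    if lam <= 0:
        raise ValueError(f"inverse-temperature scale must be positive, got {lam}")
    if not np.all(np.isfinite(costs)):
        raise ValueError("costs must be finite")
    return np.exp(log_softmax(-costs / lam))


def reward_component_binary(goal_probs: np.ndarray) -> np.ndarray:
    """Goods component when magnitudes are equal and only receipt is chancy.

    The probability that goal j pays the most is just its reward
    probability, renormalised across goals.
    """
    p = np.asarray(goal_probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("reward probabilities must lie in [0, 1]")
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate input: all reward probabilities are zero")
    return p / total


def reward_component_gaussian(
    model_1: RewardModel,
    model_2: RewardModel,
    method: str = "cumnorm",
    rng: np.random.Generator | None = None,
    n_reps: int = 100_000,
) -> float:
    """P(goal 1's session-average reward exceeds goal 2's).

    ``cumnorm`` evaluates the Normal difference law analytically: the
    difference of the two session averages is Normal with mean
    ``p1*mu1 - p2*mu2`` and variance ``s1**2/(p1*N) + s2**2/(p2*N)``.
    ``logistic`` replaces the Normal CDF by a logistic with scale ``S/1.6``
    (the classical logit approximation to the probit).  ``montecarlo``
    samples session averages from each goal's session-average law and counts
    how often goal 1 wins; it is the sampling oracle for the analytic forms
    and the fallback when a zero reward probability makes the variance
    degenerate.
    """
    if method == "montecarlo":
        if rng is None:
            raise ValueError("montecarlo method requires an rng")
        r1 = _sample_session_means(model_1, n_reps, rng)
        r2 = _sample_session_means(model_2, n_reps, rng)
        wins = np.count_nonzero(r1 > r2) + 0.5 * np.count_nonzero(r1 == r2)
        return float(wins / n_reps)

    try:
        m1, v1 = model_1.session_mean_params()
        m2, v2 = model_2.session_mean_params()
    except ValueError as exc:
        raise ValueError(
            "degenerate variance (reward_prob = 0); use method='montecarlo'"
        ) from exc
    mean_diff = m1 - m2
    scale = np.sqrt(v1 + v2)
    if scale == 0:
        return 0.5 if mean_diff == 0 else float(mean_diff > 0)
    if method == "cumnorm":
        return float(stats.norm.cdf(mean_diff / scale))
    if method == "logistic":
        return float(expit(mean_diff / (scale / 1.6)))
    raise ValueError(f"unknown method {method!r}")


def _sample_session_means(
    model: RewardModel, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw session-average rewards from the model's Normal session law.

    When ``reward_prob`` is zero every trial pays nothing and the session
    average is identically zero.
    """
    if model.reward_prob <= 0:
        return np.zeros(n_reps)
    mean, var = model.session_mean_params()
    return rng.normal(mean, np.sqrt(var), size=n_reps)


def goods_component(models: list[RewardModel], method: str = "cumnorm",
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Goods component for any number of goals with stochastic magnitudes.

    For two goals this is the pairwise session-average comparison and its
    complement.  For more goals, each goal is compared against the best
    alternative (largest expected session reward) pairwise, then the values
    are renormalised — a reduction that coincides with the pairwise law when
    only two goals compete.
    """
    n = len(models)
    if n < 2:
        raise ValueError("need at least two reward models")
    if n == 2:
        p = reward_component_gaussian(models[0], models[1], method=method, rng=rng)
        return np.array([p, 1.0 - p])
    expected = [m.reward_prob * m.reward_mean for m in models]
    vals = np.empty(n)
    for j in range(n):
        rival = max(
            (i for i in range(n) if i != j), key=lambda i: expected[i]
        )
        vals[j] = reward_component_gaussian(models[j], models[rival], method=method, rng=rng)
    return vals / vals.sum()


def combine(
    action_comp: np.ndarray,
    goods_comp: np.ndarray,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> DesirabilityWeights:
    """Multiply the two components per goal and renormalise.

    With ``noise.noise_sd > 0`` each component value is independently
    perturbed by zero-mean Gaussian noise before multiplying; every
    perturbed value is clipped from below at ``noise.floor`` so the product
    sum is always positive and the normalisation is well defined even when
    the noiseless products are all zero (the extreme reward-vs-effort
    conflict).
    """
    a = np.asarray(action_comp, dtype=float)
    g = np.asarray(goods_comp, dtype=float)
    if a.shape != g.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("components must be 1-D arrays of equal length >= 2")
    if np.any((a < 0) | (a > 1)) or np.any((g < 0) | (g > 1)):
        raise ValueError("component entries must lie in [0, 1]")
    noise = noise or NoiseSpec()
    if noise.noise_sd > 0:
        if rng is None:
            raise ValueError("noisy combination requires an rng")
        a = a + rng.normal(0.0, noise.noise_sd, size=a.shape)
        g = g + rng.normal(0.0, noise.noise_sd, size=g.shape)
    a = np.clip(a, noise.floor, None)
    g = np.clip(g, noise.floor, None)
    products = a * g
    weights = products / products.sum()
    return DesirabilityWeights(
        weights=weights,
        action_component=np.clip(a, 0.0, 1.0),
        goods_component=np.clip(g, 0.0, 1.0),
    )


def choose_lambda(costs: np.ndarray, rule: str = "cost_scale",
                  fixed_value: float = 1.0, kappa: float = 1.0) -> float:
    """Pick the inverse-temperature scale for the cost softmax.

    ``fixed`` returns ``fixed_value``; ``cost_scale`` returns
    ``kappa * mean(costs)``, which keeps the action component non-degenerate
    as cost magnitudes change with task geometry (costs here span orders of
    magnitude between far-from-goal and near-goal states).
    """
    costs = np.asarray(costs, dtype=float)
    if not np.all(np.isfinite(costs)):
        raise ValueError("costs must be finite")
    if rule == "fixed":
        if fixed_value <= 0:
            raise ValueError("fixed lambda must be positive")
        return float(fixed_value)
    if rule == "cost_scale":
        mean_cost = float(costs.mean())
        if mean_cost <= 0:
            raise ValueError("cost_scale rule needs a positive mean cost")
        return kappa * mean_cost
    raise ValueError(f"unknown lambda rule {rule!r}")
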