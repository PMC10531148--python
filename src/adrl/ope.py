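"""Off-policy evaluation of a target policy from logged trajectories.

The default estimator is stepwise (per-decision) weighted importance
sampling.  For trajectory i with logged states s_t, actions a_t and rewards
r_t, the cumulative importance ratio at step t is

    w_{i,t} = prod_{u<=t} pi(a_u|s_u) / pi_b(a_u|s_u)

and the value estimate is

    V = sum_t gamma^t * sum_i (w_{i,t} / Z_t) * r_{i,t},   Z_t = sum_i w_{i,t},

where a trajectory shorter than t keeps its final cumulative weight with
zero reward.  Carrying the final weight makes the estimator collapse to the
plain empirical mean discounted return when target == behavior, even with
variable-length records.  A step whose normalizer is exactly zero (the
target has no support on any logged action prefix) contributes 0 and is
flagged in the diagnostics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DomainError
from .policies import TabularPolicy
from .trajectory_mdp import Trajectory, discounted_return


@dataclass
class OPEResult:
    """Step-WIS value estimate with full weight diagnostics."""

    value: float
    weights: np.ndarray  # (n_traj, T) cumulative ratios, final weight carried
    normalizers: np.ndarray  # (T,) sum of weights per step
    ess: np.ndarray  # (T,) effective sample size (sum w)^2 / sum w^2
    n_trajectories: int
    no_support_steps: list[int] = field(default_factory=list)

    @property
    def no_support(self) -> bool:
        return len(self.no_support_steps) > 0


def _padded_log(
    target: TabularPolicy,
    behavior: TabularPolicy,
    trajectories: list[Trajectory],
) -> tuple[np.ndarray, np.ndarray]:
    """(cumulative weights, rewards) padded to the longest record.

    Past a trajectory's end the per-step ratio is 1 (weight carried) and the
    reward 0.
    """
    n = len(trajectories)
    T = max(len(t) for t in trajectories)
    ratios = np.ones((n, T))
    rewards = np.zeros((n, T))
    for i, traj in enumerate(trajectories):
        for t, step in enumerate(traj.transitions):
            pb = behavior.probs[step.state, step.action]
            if pb <= 0.0:
                raise DataError(
                    f"logged action {step.action} at state {step.state} has zero "
                    "behavior probability; behavior policy is inconsistent with the log"
                )
            ratios[i, t] = target.probs[step.state, step.action] / pb
            rewards[i, t] = step.reward
    return np.cumprod(ratios, axis=1), rewards


def _estimate(weights: np.ndarray, rewards: np.ndarray, gamma: float):
    T = weights.shape[1]
    normalizers = weights.sum(axis=0)
    sq = (weights**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ess = np.where(sq > 0, normalizers**2 / sq, 0.0)
    no_support = [t for t in range(T) if normalizers[t] == 0.0]
    discounts = gamma ** np.arange(T)
    per_step = np.zeros(T)
    ok = normalizers > 0
    per_step[ok] = (weights[:, ok] * rewards[:, ok]).sum(axis=0) / normalizers[ok]
    value = float((discounts * per_step).sum())
    return value, normalizers, ess, no_support


def step_wis(
    target: TabularPolicy,
    behavior: TabularPolicy,
    trajectories: list[Trajectory],
    gamma: float,
    estimator: str = "step_wis",
    clip: float | None = None,
) -> OPEResult:
    """Estimate the value of ``target`` from trajectories logged under ``behavior``.

    ``estimator`` selects the variant: ``step_wis`` (default, per-decision
    self-normalized), ``wis`` (trajectory-wise weighted IS), or ``is`` (plain
    unnormalized IS).  ``clip`` optionally caps cumulative ratios.
    """
    if not 0.0 <= gamma < 1.0:
        raise DomainError(f"gamma must be in [0, 1), got {gamma}")
    if estimator not in ("step_wis", "wis", "is"):
        raise DomainError(f"unknown estimator {estimator!r}")
    if not trajectories:
        raise DataError("step_wis requires at least one trajectory")
    weights, rewards = _padded_log(target, behavior, trajectories)
    if clip is not None:
        weights = np.minimum(weights, clip)
    n = len(trajectories)
    T = weights.shape[1]
    discounts = gamma ** np.arange(T)
    if estimator == "step_wis":
        value, normalizers, ess, no_support = _estimate(weights, rewards, gamma)
    else:
        returns = (discounts * rewards).sum(axis=1)
        w_final = weights[:, -1]
        normalizers = weights.sum(axis=0)
        sq = (weights**2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ess = np.where(sq > 0, normalizers**2 / sq, 0.0)
        if estimator == "wis":
            z = w_final.sum()
            no_support = [0] if z == 0.0 else []
            value = float((w_final * returns).sum() / z) if z > 0 else 0.0
        else:  # plain IS
            no_support = [0] if w_final.sum() == 0.0 else []
            value = float((w_final * returns).mean())
    return OPEResult(
        value=value,
        weights=weights,
        normalizers=normalizers,
        ess=ess,
        n_trajectories=n,
        no_support_steps=no_support,
    )


def on_policy_value(trajectories: list[Trajectory], gamma: float) -> float:
    """Plain empirical mean discounted return of the logged trajectories."""
    if not trajectories:
        raise DataError("on_policy_value requires at least one trajectory")
    return float(np.mean([discounted_return(t.rewards, gamma) for t in trajectories]))
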