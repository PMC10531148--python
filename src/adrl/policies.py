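"""Tabular policies and the five solvers compared in the study.

All policies are rows of action probabilities over the six medication
classes; deterministic policies are one-hot.  Everything here respects the
*support restriction*: an empirical model knows nothing about (state, action)
pairs that were never logged, so greedy improvement only ranks observed
actions, and states with no observed action at all fall back to NO_DRUGS.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .actions import N_ACTIONS, NO_DRUGS
from .errors import DataError, DomainError
from .trajectory_mdp import Trajectory, TransitionModel

logger = logging.getLogger(__name__)

FALLBACK_ACTION = NO_DRUGS

# direct linear solve below this many states, power iteration beyond
_LINEAR_SOLVE_MAX_STATES = 200
_ITERATIVE_TOL = 1e-8


@dataclass
class TabularPolicy:
    """pi(a|s) as an (n_states, n_actions) row-stochastic matrix."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise DomainError("policy matrix must be 2-dimensional")
        if np.any(self.probs < -1e-15):
            raise DomainError("policy probabilities must be nonnegative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise DomainError("every policy row must sum to 1")

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    @property
    def n_actions(self) -> int:
        return self.probs.shape[1]

    @property
    def is_deterministic(self) -> bool:
        return bool(np.all(np.isin(self.probs, (0.0, 1.0))))

    def actions(self) -> np.ndarray:
        """Per-state argmax action (the policy itself when deterministic)."""
        return self.probs.argmax(axis=1)

    @classmethod
    def deterministic(cls, actions, n_actions: int = N_ACTIONS) -> "TabularPolicy":
        actions = np.asarray(actions, dtype=int)
        probs = np.zeros((len(actions), n_actions))
        probs[np.arange(len(actions)), actions] = 1.0
        return cls(probs)

    @classmethod
    def uniform(cls, n_states: int, n_actions: int = N_ACTIONS) -> "TabularPolicy":
        return cls(np.full((n_states, n_actions), 1.0 / n_actions))


@dataclass
class ValueFunction:
    """State values v(s) in discounted MMSE points."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise DomainError("value function must be finite")


@dataclass
class QTable:
    """Q(s,a) with its learning rate and per-pair update counts."""

    q: np.ndarray
    alpha: float
    visit_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.visit_counts is None:
            self.visit_counts = np.zeros_like(self.q, dtype=int)


def _check_gamma(gamma: float) -> None:
    if not 0.0 <= gamma < 1.0:
        raise DomainError(f"gamma must be in [0, 1), got {gamma}")


def policy_evaluation(policy: TabularPolicy, model: TransitionModel, gamma: float) -> ValueFunction:
    """Solve v = r_pi + gamma * P_pi v for the given policy on the empirical model.

    States with no observed action are treated as absorbing with zero reward
    (their value is 0).  Policy mass on an unobserved action of an otherwise
    observed state violates the support precondition and raises.
    """
    _check_gamma(gamma)
    S, A = model.support.shape
    if policy.probs.shape != (S, A):
        raise DataError("policy shape does not match model")
    off_support = (~model.support) & (policy.probs > 1e-12)
    visited = model.support.any(axis=1)
    if np.any(off_support[visited]):
        bad = np.argwhere(off_support & visited[:, None])[0]
        raise DataError(
            f"policy puts probability on unobserved pair (state {bad[0]}, action {bad[1]})"
        )
    pi = np.where(model.support, policy.probs, 0.0)
    r_pi = (pi * model.rewards).sum(axis=1)
    P_pi = np.einsum("sa,sat->st", pi, model.probs)
    # unvisited states: absorbing, zero reward
    P_pi[~visited] = 0.0
    idx = np.where(~visited)[0]
    P_pi[idx, idx] = 1.0
    r_pi[idx] = 0.0
    if S <= _LINEAR_SOLVE_MAX_STATES:
        v = np.linalg.solve(np.eye(S) - gamma * P_pi, r_pi)
    else:
        v = np.zeros(S)
        for _ in range(100_000):
            v_new = r_pi + gamma * (P_pi @ v)
            if np.max(np.abs(v_new - v)) < _ITERATIVE_TOL:
                v = v_new
                break
            v = v_new
    return ValueFunction(v)


def q_values(value: ValueFunction, model: TransitionModel, gamma: float) -> np.ndarray:
    """One-step lookahead Q(s,a) = R(s,a) + gamma * sum_s' P(s'|s,a) v(s');
    -inf outside the observed support."""
    _check_gamma(gamma)
    q = model.rewards + gamma * np.einsum("sat,t->sa", model.probs, value.values)
    return np.where(model.support, q, -np.inf)


def policy_improvement(value: ValueFunction, model: TransitionModel, gamma: float) -> TabularPolicy:
    """Greedy deterministic policy over observed actions; ties and states with
    no observed action resolve to the lowest index / NO_DRUGS."""
    q = q_values(value, model, gamma)
    visited = model.support.any(axis=1)
    actions = np.where(visited, q.argmax(axis=1), FALLBACK_ACTION)
    if not visited.all():
        logger.warning(
            "policy_improvement: %d states have no observed action; falling back to NO_DRUGS",
            int((~visited).sum()),
        )
    return TabularPolicy.deterministic(actions, model.n_actions)


def policy_iteration(
    model: TransitionModel, gamma: float, max_iter: int = 1000
) -> TabularPolicy:
    """Alternate exact evaluation and greedy improvement until the policy is stable."""
    _check_gamma(gamma)
    visited = model.support.any(axis=1)
    # start from the lowest observed action per state (deterministic, supported)
    first_obs = np.where(visited, model.support.argmax(axis=1), FALLBACK_ACTION)
    policy = TabularPolicy.deterministic(first_obs, model.n_actions)
    for _ in range(max_iter):
        value = policy_evaluation(policy, model, gamma)
        improved = policy_improvement(value, model, gamma)
        if np.array_equal(improved.actions(), policy.actions()):
            return improved
        policy = improved
    raise RuntimeError("policy iteration did not converge")  # pragma: no cover


def behavior_policy(
    trajectories: list[Trajectory],
    n_states: int,
    n_actions: int = N_ACTIONS,
) -> TabularPolicy:
    """Empirical action frequencies per state; unvisited states get uniform rows."""
    if not any(len(t) for t in trajectories):
        raise DataError("behavior_policy requires at least one transition")
    counts = np.zeros((n_states, n_actions))
    for traj in trajectories:
        for t in traj.transitions:
            counts[t.state, t.action] += 1
    totals = counts.sum(axis=1)
    probs = np.full((n_states, n_actions), 1.0 / n_actions)
    visited = totals > 0
    probs[visited] = counts[visited] / totals[visited, None]
    return TabularPolicy(probs)


def clinician_policy(model: TransitionModel, behavior: TabularPolicy, gamma: float) -> TabularPolicy:
    """One policy-evaluation + one policy-improvement step on the empirical
    transition probabilities, starting from the clinicians' observed
    (behavior) policy — a data-driven proxy for clinical practice."""
    value = policy_evaluation(behavior, model, gamma)
    return policy_improvement(value, model, gamma)


def zero_policy(n_states: int, n_actions: int = N_ACTIONS) -> TabularPolicy:
    """Prescribe nothing everywhere."""
    return TabularPolicy.deterministic(np.full(n_states, NO_DRUGS), n_actions)


def random_policy(n_states: int, n_actions: int = N_ACTIONS) -> TabularPolicy:
    """Uniform over the six classes everywhere."""
    return TabularPolicy.uniform(n_states, n_actions)


def q_learning(
    trajectories: list[Trajectory],
    gamma: float,
    alpha: float = 0.05,
    n_passes: int = 50,
    seed: int = 0,
    n_states: int | None = None,
    n_actions: int = N_ACTIONS,
    bootstrap_terminals: bool = False,
) -> QTable:
    """Off-policy temporal-difference learning by replaying the logged transitions.

    Q starts at zero and every pass sweeps all logged transitions in a fresh
    seeded random order, applying
    ``Q(s,a) += alpha * (r + gamma * max_a' Q(s',a') - Q(s,a))``
    with the max restricted to actions observed at s' anywhere in the log.
    The last transition of each trajectory is an episode end: its target is
    the raw reward (value 0 beyond the record).  Set ``bootstrap_terminals``
    when trajectories are truncations of a continuing process rather than
    true episode ends.
    """
    _check_gamma(gamma)
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if n_passes < 1:
        raise DomainError("n_passes must be >= 1")
    steps = [
        (t.state, t.action, t.reward, t.next_state, i == len(traj.transitions) - 1)
        for traj in trajectories
        for i, t in enumerate(traj.transitions)
    ]
    if not steps:
        raise DataError("q_learning requires at least one transition")
    if n_states is None:
        n_states = 1 + max(max(s, ns) for s, _, _, ns, _ in steps)

    observed: list[list[int]] = [[] for _ in range(n_states)]
    counts = np.zeros((n_states, n_actions), dtype=int)
    for s, a, _, _, _ in steps:
        if a not in observed[s]:
            observed[s].append(a)
        counts[s, a] += 1
    for acts in observed:
        acts.sort()

    rng = np.random.default_rng(seed)
    # plain-Python hot loop: lists of floats are markedly faster than ndarray
    # scalar indexing for this inherently sequential update
    q: list[list[float]] = [[0.0] * n_actions for _ in range(n_states)]
    s_arr = [st[0] for st in steps]
    a_arr = [st[1] for st in steps]
    r_arr = [st[2] for st in steps]
    ns_arr = [st[3] for st in steps]
    term_arr = [st[4] and not bootstrap_terminals for st in steps]
    n = len(steps)
    for _ in range(n_passes):
        order = rng.permutation(n)
        for idx in order:
            s = s_arr[idx]
            a = a_arr[idx]
            target = r_arr[idx]
            if not term_arr[idx]:
                ns = ns_arr[idx]
                acts = observed[ns]
                if acts:
                    row = q[ns]
                    target += gamma * max(row[j] for j in acts)
            q[s][a] += alpha * (target - q[s][a])
    return QTable(q=np.array(q), alpha=alpha, visit_counts=counts * n_passes)


def greedy_policy(qtable: QTable) -> TabularPolicy:
    """One-hot argmax per state over actions updated at least once; states with
    no visits fall back to NO_DRUGS; ties go to the lowest action index."""
    if not np.all(np.isfinite(qtable.q)):
        raise DomainError("Q-table must be finite")
    S, A = qtable.q.shape
    masked = np.where(qtable.visit_counts > 0, qtable.q, -np.inf)
    visited = (qtable.visit_counts > 0).any(axis=1)
    actions = np.where(visited, masked.argmax(axis=1), FALLBACK_ACTION)
    return TabularPolicy.deterministic(actions, A)


def bellman_optimality_residual(qtable: QTable, model: TransitionModel, gamma: float) -> float:
    """Max |Q(s,a) - (R + gamma * sum P max_a' Q)| over the observed support."""
    _check_gamma(gamma)
    masked = np.where(qtable.visit_counts > 0, qtable.q, -np.inf)
    vmax = np.where(np.isfinite(masked).any(axis=1), masked.max(axis=1), 0.0)
    target = model.rewards + gamma * np.einsum("sat,t->sa", model.probs, vmax)
    resid = np.abs(qtable.q - target)[model.support]
    return float(resid.max()) if resid.size else 0.0


def enumerate_deterministic_policies(n_states: int, n_actions: int):
    """All n_actions**n_states deterministic action assignments (small MDPs only)."""
    return itertools.product(range(n_actions), repeat=n_states)
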