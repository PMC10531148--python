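"""From state-labelled visit sequences to a logged tabular MDP.

Each consecutive pair of visits of one patient yields one logged transition
(s, a, r, s'): the action is the medication class recorded at the earlier
visit (it labels the interval that follows), and the reward is the MMSE
change over that interval, MMSE(later) - MMSE(earlier).  Pairs that touch a
pruned/unassigned state are dropped.  The empirical transition model is the
maximum-likelihood tabular estimate P(s'|s,a) = N(s,a,s') / N(s,a,.) with
per-(s,a) mean rewards.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actions import N_ACTIONS
from .errors import DataError, DomainError
from .state_space import UNASSIGNED

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.3


@dataclass(frozen=True)
class Transition:
    state: int
    action: int
    reward: float
    next_state: int


@dataclass
class Trajectory:
    """One patient's ordered transitions; consecutive steps chain."""

    patient_id: object
    transitions: list[Transition]
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        for a, b in zip(self.transitions, self.transitions[1:]):
            if a.next_state != b.state:
                raise DataError(
                    f"trajectory for patient {self.patient_id!r} does not chain: "
                    f"{a.next_state} != {b.state}"
                )

    def __len__(self) -> int:
        return len(self.transitions)

    @property
    def rewards(self) -> list[float]:
        return [t.reward for t in self.transitions]

    def returns(self) -> list[float]:
        """Discounted return G_t from every step t to the end of the record."""
        return [discounted_return(self.rewards[t:], self.gamma) for t in range(len(self))]


def discounted_return(rewards, gamma: float) -> float:
    """Sum_k gamma^k * R_{t+1+k} over the given reward sequence."""
    if not 0.0 <= gamma < 1.0:
        raise DomainError(f"gamma must be in [0, 1), got {gamma}")
    total = 0.0
    for r in reversed(list(rewards)):
        total = r + gamma * total
    return total


def build_transitions(
    visits: pd.DataFrame,
    *,
    state_col: str = "STATE",
    action_col: str = "ACTION",
    reward_col: str = "MMSE",
    id_col: str = "RID",
    month_col: str = "MONTH",
    gamma: float = DEFAULT_GAMMA,
) -> list[Trajectory]:
    """One trajectory per patient from a state/action-labelled visit table.

    A transition is emitted for every consecutive visit pair whose two states
    are both assigned; rewards are raw MMSE differences with no per-interval
    time scaling.  Patients left with no usable pair are skipped (counted in
    a log message, not an error).
    """
    for col in (state_col, action_col, reward_col, id_col, month_col):
        if col not in visits.columns:
            raise DataError(f"visit table lacks required column {col!r}")
    trajectories: list[Trajectory] = []
    n_skipped = 0
    n_dropped_pairs = 0
    for rid, group in visits.groupby(id_col, sort=True):
        group = group.sort_values(month_col)
        states = group[state_col].to_numpy()
        actions = group[action_col].to_numpy()
        mmse = group[reward_col].to_numpy(dtype=float)
        steps: list[Transition] = []
        for i in range(len(group) - 1):
            if states[i] == UNASSIGNED or states[i + 1] == UNASSIGNED:
                n_dropped_pairs += 1
                # an unassigned visit breaks the chain: flush what we have
                if steps:
                    trajectories.append(Trajectory(rid, steps, gamma))
                    steps = []
                continue
            steps.append(
                Transition(int(states[i]), int(actions[i]), float(mmse[i + 1] - mmse[i]), int(states[i + 1]))
            )
        if steps:
            trajectories.append(Trajectory(rid, steps, gamma))
        else:
            n_skipped += 1
    if n_skipped or n_dropped_pairs:
        logger.info(
            "build_transitions: skipped %d patients without usable pairs, dropped %d pairs at unassigned states",
            n_skipped,
            n_dropped_pairs,
        )
    return trajectories


@dataclass
class TransitionModel:
    """Empirical tabular MDP: counts, MLE transition probabilities, mean rewards.

    ``support[s, a]`` is True iff the pair was logged at least once; solvers
    must not invent dynamics outside the support.
    """

    counts: np.ndarray  # (S, A, S) visit counts
    probs: np.ndarray  # (S, A, S) rows normalized where observed, else 0
    rewards: np.ndarray  # (S, A) mean observed reward, 0 where unobserved
    support: np.ndarray  # (S, A) bool
    n_states: int = field(init=False)
    n_actions: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_states, self.n_actions = self.support.shape
        row_sums = self.probs.sum(axis=2)
        if not np.allclose(row_sums[self.support], 1.0, atol=1e-12):
            raise DataError("observed transition rows must sum to 1")

    @classmethod
    def from_arrays(cls, probs: np.ndarray, rewards: np.ndarray) -> "TransitionModel":
        """Fully supported model from known tensors (e.g. a ground-truth MDP)."""
        probs = np.asarray(probs, dtype=float)
        rewards = np.asarray(rewards, dtype=float)
        support = np.ones(rewards.shape, dtype=bool)
        counts = np.ones_like(probs)
        return cls(counts=counts, probs=probs, rewards=rewards, support=support)


def estimate_transition_model(
    trajectories: list[Trajectory],
    n_states: int | None = None,
    n_actions: int = N_ACTIONS,
) -> TransitionModel:
    """Maximum-likelihood P(s'|s,a) and mean rewards from logged trajectories."""
    all_steps = [t for traj in trajectories for t in traj.transitions]
    if not all_steps:
        raise DataError("estimate_transition_model requires at least one transition")
    if n_states is None:
        n_states = 1 + max(max(t.state, t.next_state) for t in all_steps)
    counts = np.zeros((n_states, n_actions, n_states))
    reward_sums = np.zeros((n_states, n_actions))
    for t in all_steps:
        counts[t.state, t.action, t.next_state] += 1
        reward_sums[t.state, t.action] += t.reward
    pair_counts = counts.sum(axis=2)
    support = pair_counts > 0
    probs = np.zeros_like(counts)
    probs[support] = counts[support] / pair_counts[support, None]
    rewards = np.zeros((n_states, n_actions))
    rewards[support] = reward_sums[support] / pair_counts[support]
    return TransitionModel(counts=counts, probs=probs, rewards=rewards, support=support)


def transitions_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Flat four-column export (plus patient id) of all logged transitions."""
    rows = [
        (traj.patient_id, t.state, t.action, t.reward, t.next_state)
        for traj in trajectories
        for t in traj.transitions
    ]
    return pd.DataFrame(rows, columns=["RID", "state", "action", "reward", "next_state"])
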