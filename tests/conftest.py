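"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's solver code paths: policy
values are computed by a direct linear solve and optimal policies by
exhaustive enumeration over all deterministic policies, so solver tests
compare two independent routes to the same quantity.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import adrl

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# -- independent oracles --------------------------------------------------


def oracle_policy_value(probs: np.ndarray, rewards: np.ndarray, gamma: float, actions) -> np.ndarray:
    """v of a deterministic policy by direct linear solve on known tensors."""
    S = probs.shape[0]
    actions = np.asarray(actions, dtype=int)
    P = probs[np.arange(S), actions]
    r = rewards[np.arange(S), actions]
    return np.linalg.solve(np.eye(S) - gamma * P, r)


def oracle_optimal(probs: np.ndarray, rewards: np.ndarray, gamma: float):
    """(best value function, best deterministic policy) by brute-force
    enumeration of every action assignment."""
    S, A = rewards.shape
    best_v, best_actions = None, None
    for assignment in itertools.product(range(A), repeat=S):
        v = oracle_policy_value(probs, rewards, gamma, assignment)
        if best_v is None or v.sum() > best_v.sum():
            best_v, best_actions = v, np.array(assignment)
    # elementwise max over policies equals the optimum of the best policy for
    # a finite MDP, but recompute defensively as the per-state max
    stacked = np.array(
        [
            oracle_policy_value(probs, rewards, gamma, a)
            for a in itertools.product(range(A), repeat=S)
        ]
    )
    return stacked.max(axis=0), best_actions


def random_mdp(rng: np.random.Generator, n_states: int, n_actions: int):
    """Random ergodic MDP: Dirichlet transition rows, rewards in [-3, 3]."""
    probs = rng.dirichlet(np.ones(n_states), size=(n_states, n_actions))
    rewards = rng.uniform(-3.0, 3.0, size=(n_states, n_actions))
    return probs, rewards


def random_deterministic_mdp(rng: np.random.Generator, n_states: int, n_actions: int):
    """Random MDP with deterministic transitions (one successor per pair)."""
    nxt = rng.integers(0, n_states, size=(n_states, n_actions))
    probs = np.zeros((n_states, n_actions, n_states))
    for s in range(n_states):
        for a in range(n_actions):
            probs[s, a, nxt[s, a]] = 1.0
    rewards = rng.uniform(-3.0, 3.0, size=(n_states, n_actions))
    return probs, rewards, nxt


def walk_trajectories(nxt, rewards, rng, length: int = 12):
    """Replay log for a deterministic MDP: one random-action walk per (s, a)
    start, so every pair is logged at least once."""
    S, A = rewards.shape
    trajs = []
    for s0 in range(S):
        for a0 in range(A):
            s, a = s0, a0
            steps = []
            for _ in range(length):
                ns = int(nxt[s, a])
                steps.append(adrl.Transition(s, a, float(rewards[s, a]), ns))
                s = ns
                a = int(rng.integers(A))
            trajs.append(adrl.Trajectory(f"walk-{s0}-{a0}", steps))
    return trajs


# -- fixtures -------------------------------------------------------------


@pytest.fixture(scope="session")
def true_mdp():
    return adrl.default_true_mdp(5)


@pytest.fixture(scope="session")
def small_cohort(true_mdp):
    """300-patient synthetic cohort (raw, with ground-truth columns)."""
    config = adrl.GeneratorConfig(n_patients=300, seed=42)
    return adrl.generate_cohort(config, true_mdp)


@pytest.fixture(scope="session")
def prepared_cohort(small_cohort):
    """Eligible, forward-filled, action-coded version of the small cohort."""
    return adrl.prepare_visits(small_cohort)


@pytest.fixture()
def toy_visits():
    """Hand-written four-patient visit table exercising edge cases."""
    rows = [
        # patient 1: two complete visits
        dict(RID=1, MONTH=0, MMSE=24, ADAS13=20, RAVLT_IMMEDIATE=30, RAVLT_LEARNING=4,
             CDRSB=2, MOCA=22, FDG=1.1, AGE=70, DX="MCI", HYPERTENSION=0, DEPRESSION=0,
             VISCODE="bl", MEDICATIONS="donepezil"),
        dict(RID=1, MONTH=6, MMSE=26, ADAS13=18, RAVLT_IMMEDIATE=32, RAVLT_LEARNING=5,
             CDRSB=1.5, MOCA=24, FDG=1.15, AGE=70.5, DX="MCI", HYPERTENSION=0, DEPRESSION=0,
             VISCODE="m06", MEDICATIONS="donepezil"),
        # patient 2: single visit -> excluded
        dict(RID=2, MONTH=0, MMSE=28, ADAS13=10, RAVLT_IMMEDIATE=45, RAVLT_LEARNING=6,
             CDRSB=0.5, MOCA=27, FDG=1.3, AGE=65, DX="CN", HYPERTENSION=1, DEPRESSION=0,
             VISCODE="bl", MEDICATIONS=""),
        # patient 3: MMSE missing at every visit -> unfillable, excluded
        dict(RID=3, MONTH=0, MMSE=np.nan, ADAS13=30, RAVLT_IMMEDIATE=20, RAVLT_LEARNING=2,
             CDRSB=5, MOCA=15, FDG=0.9, AGE=75, DX="AD", HYPERTENSION=0, DEPRESSION=1,
             VISCODE="bl", MEDICATIONS="memantine"),
        dict(RID=3, MONTH=6, MMSE=np.nan, ADAS13=32, RAVLT_IMMEDIATE=18, RAVLT_LEARNING=2,
             CDRSB=6, MOCA=14, FDG=0.85, AGE=75.5, DX="AD", HYPERTENSION=0, DEPRESSION=1,
             VISCODE="m06", MEDICATIONS="memantine"),
        # patient 4: a mid-sequence gap that carry-forward can fill
        dict(RID=4, MONTH=0, MMSE=24, ADAS13=25, RAVLT_IMMEDIATE=25, RAVLT_LEARNING=3,
             CDRSB=3, MOCA=20, FDG=1.0, AGE=80, DX="MCI", HYPERTENSION=1, DEPRESSION=1,
             VISCODE="bl", MEDICATIONS="lisinopril"),
        dict(RID=4, MONTH=6, MMSE=np.nan, ADAS13=np.nan, RAVLT_IMMEDIATE=24, RAVLT_LEARNING=3,
             CDRSB=3.5, MOCA=19, FDG=0.98, AGE=80.5, DX="MCI", HYPERTENSION=1, DEPRESSION=1,
             VISCODE="m06", MEDICATIONS="vitamin e"),
        dict(RID=4, MONTH=12, MMSE=22, ADAS13=28, RAVLT_IMMEDIATE=22, RAVLT_LEARNING=2,
             CDRSB=4, MOCA=18, FDG=0.95, AGE=81, DX="MCI", HYPERTENSION=1, DEPRESSION=1,
             VISCODE="m12", MEDICATIONS="donepezil|memantine"),
    ]
    return pd.DataFrame(rows)
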