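"""Solver tests: exact evaluation/improvement/iteration against brute-force
oracles, Q-learning consistency, and the reference policies."""
import numpy as np
import pytest

import adrl
from adrl import actions as act
from adrl.errors import DataError, DomainError
from adrl.policies import (
    QTable,
    TabularPolicy,
    ValueFunction,
    behavior_policy,
    bellman_optimality_residual,
    clinician_policy,
    greedy_policy,
    policy_evaluation,
    policy_improvement,
    policy_iteration,
    q_learning,
    random_policy,
    zero_policy,
)
from adrl.trajectory_mdp import Trajectory, Transition, TransitionModel, estimate_transition_model

from conftest import (
    oracle_optimal,
    oracle_policy_value,
    random_deterministic_mdp,
    random_mdp,
    walk_trajectories,
)


def model_from(probs, rewards):
    return TransitionModel.from_arrays(probs, rewards)


class TestPolicyEvaluation:
    def test_self_loop_geometric_series(self):
        probs = np.ones((1, 1, 1))
        rewards = np.ones((1, 1))
        model = model_from(probs, rewards)
        v = policy_evaluation(TabularPolicy.deterministic([0], 1), model, 0.3)
        assert v.values[0] == pytest.approx(1.0 / 0.7)

    def test_myopic_limit_is_immediate_reward(self):
        rng = np.random.default_rng(0)
        probs, rewards = random_mdp(rng, 3, 2)
        model = model_from(probs, rewards)
        policy = TabularPolicy.uniform(3, 2)
        v = policy_evaluation(policy, model, 0.0)
        np.testing.assert_allclose(v.values, (policy.probs * rewards).sum(axis=1))

    def test_two_state_absorbing_chain_hand_solve(self):
        # state 0 -> state 1 with reward 1; state 1 absorbs with reward 0:
        # v = (1 + gamma*0, 0) = (1, 0)
        probs = np.zeros((2, 1, 2))
        probs[0, 0, 1] = 1.0
        probs[1, 0, 1] = 1.0
        rewards = np.array([[1.0], [0.0]])
        v = policy_evaluation(
            TabularPolicy.deterministic([0, 0], 1), model_from(probs, rewards), 0.3
        )
        np.testing.assert_allclose(v.values, [1.0, 0.0], atol=1e-12)

    def test_gamma_domain_error(self):
        model = model_from(np.ones((1, 1, 1)), np.ones((1, 1)))
        with pytest.raises(DomainError):
            policy_evaluation(TabularPolicy.deterministic([0], 1), model, 1.0)

    def test_mass_on_unobserved_action_rejected(self):
        trajs = [Trajectory(1, [Transition(0, 0, 1.0, 0)])]
        model = estimate_transition_model(trajs, n_states=1, n_actions=2)
        with pytest.raises(DataError):
            policy_evaluation(TabularPolicy.deterministic([1], 2), model, 0.3)


class TestPolicyImprovement:
    def test_myopic_limit_is_reward_argmax(self):
        rng = np.random.default_rng(1)
        probs, rewards = random_mdp(rng, 4, 3)
        model = model_from(probs, rewards)
        improved = policy_improvement(ValueFunction(np.zeros(4)), model, 0.0)
        np.testing.assert_array_equal(improved.actions(), rewards.argmax(axis=1))

    def test_identical_actions_tie_break_to_zero(self):
        probs = np.repeat(np.ones((2, 1, 2)) * 0.5, 3, axis=1)
        rewards = np.ones((2, 3))
        improved = policy_improvement(
            ValueFunction(np.zeros(2)), model_from(probs, rewards), 0.3
        )
        assert (improved.actions() == 0).all()

    def test_strictly_dominant_action_selected(self):
        rng = np.random.default_rng(2)
        probs, rewards = random_mdp(rng, 3, 3)
        rewards[:, 1] = 10.0  # dominate both immediately and prospectively
        model = model_from(probs, rewards)
        policy = policy_iteration(model, 0.3)
        assert (policy.actions() == 1).all()


class TestPolicyIteration:
    @pytest.mark.parametrize("n_states,n_actions", [(2, 2), (3, 3), (4, 3)])
    def test_matches_brute_force_enumeration(self, n_states, n_actions):
        rng = np.random.default_rng(n_states * 10 + n_actions)
        for _ in range(5):
            probs, rewards = random_mdp(rng, n_states, n_actions)
            model = model_from(probs, rewards)
            policy = policy_iteration(model, 0.3)
            v_star, _ = oracle_optimal(probs, rewards, 0.3)
            v = oracle_policy_value(probs, rewards, 0.3, policy.actions())
            np.testing.assert_allclose(v, v_star, atol=1e-8)

    def test_monotone_improvement(self):
        rng = np.random.default_rng(9)
        probs, rewards = random_mdp(rng, 4, 3)
        model = model_from(probs, rewards)
        policy = TabularPolicy.deterministic([0, 0, 0, 0], 3)
        for _ in range(5):
            v = policy_evaluation(policy, model, 0.3)
            improved = policy_improvement(v, model, 0.3)
            v_new = policy_evaluation(improved, model, 0.3)
            assert np.all(v_new.values >= v.values - 1e-10)
            policy = improved

    def test_support_restriction_single_action_log(self):
        trajs = [
            Trajectory(1, [Transition(0, 2, 1.0, 1), Transition(1, 2, -1.0, 0)]),
        ]
        model = estimate_transition_model(trajs, n_states=2)
        policy = policy_iteration(model, 0.3)
        assert (policy.actions() == 2).all()


class TestQLearning:
    def test_single_update_formula(self):
        trajs = [Trajectory(1, [Transition(0, 1, 2.0, 0)])]
        qt = q_learning(trajs, gamma=0.3, alpha=0.05, n_passes=1, n_states=1)
        assert qt.q[0, 1] == pytest.approx(0.05 * 2.0)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2])
    def test_alpha_domain(self, alpha):
        trajs = [Trajectory(1, [Transition(0, 0, 1.0, 0)])]
        with pytest.raises(DomainError):
            q_learning(trajs, gamma=0.3, alpha=alpha, n_passes=1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        probs, rewards, nxt = random_deterministic_mdp(rng, 3, 2)
        trajs = walk_trajectories(nxt, rewards, np.random.default_rng(0), length=8)
        a = q_learning(trajs, 0.3, 0.05, 20, seed=11, bootstrap_terminals=True)
        b = q_learning(trajs, 0.3, 0.05, 20, seed=11, bootstrap_terminals=True)
        np.testing.assert_array_equal(a.q, b.q)

    def test_replayed_chain_matches_exact_solver(self):
        """On a deterministic MDP replayed to convergence, greedy(Q) equals
        policy iteration on the same data and the Bellman residual is tiny."""
        rng = np.random.default_rng(4)
        probs, rewards, nxt = random_deterministic_mdp(rng, 3, 3)
        trajs = walk_trajectories(nxt, rewards, np.random.default_rng(1), length=10)
        model = estimate_transition_model(trajs, 3, 3)
        qt = q_learning(
            trajs, 0.3, alpha=0.05, n_passes=500, seed=0, n_actions=3, bootstrap_terminals=True
        )
        assert bellman_optimality_residual(qt, model, 0.3) < 1e-3
        np.testing.assert_array_equal(
            greedy_policy(qt).actions(), policy_iteration(model, 0.3).actions()
        )

    def test_greedy_tie_and_fallback_rules(self):
        q = np.array([[0.1, 0.5, 0.2, 0.5, 0.0, 0.0], np.zeros(6)])
        counts = np.array([[1, 1, 1, 1, 1, 1], [0, 0, 0, 0, 0, 0]])
        policy = greedy_policy(QTable(q=q, alpha=0.05, visit_counts=counts))
        assert policy.actions()[0] == 1  # tie between 1 and 3 -> lowest index
        assert policy.actions()[1] == act.NO_DRUGS  # unvisited state falls back

    def test_greedy_ignores_unvisited_actions(self):
        q = np.array([[0.0, 9.9, 0.3, 0.0, 0.0, 0.0]])
        counts = np.array([[3, 0, 3, 0, 0, 0]])  # action 1 never actually updated
        policy = greedy_policy(QTable(q=q, alpha=0.05, visit_counts=counts))
        assert policy.actions()[0] == 2


class TestReferencePolicies:
    def test_behavior_frequencies(self):
        trajs = [
            Trajectory(
                1,
                [
                    Transition(0, 0, 0.0, 0),
                    Transition(0, 0, 0.0, 0),
                    Transition(0, 2, 0.0, 0),
                ],
            )
        ]
        policy = behavior_policy(trajs, n_states=2)
        np.testing.assert_allclose(policy.probs[0], [2 / 3, 0, 1 / 3, 0, 0, 0])
        np.testing.assert_allclose(policy.probs[1], np.full(6, 1 / 6))
        np.testing.assert_allclose(policy.probs.sum(axis=1), 1.0)

    def test_zero_and_random_policies(self):
        zero = zero_policy(3)
        assert (zero.actions() == act.NO_DRUGS).all() and zero.is_deterministic
        rand = random_policy(3)
        np.testing.assert_allclose(rand.probs, 1 / 6)
        np.testing.assert_allclose(zero.probs.sum(axis=1), 1.0)
        np.testing.assert_allclose(rand.probs.sum(axis=1), 1.0)

    def test_clinician_myopic_limit(self):
        rng = np.random.default_rng(6)
        probs, rewards = random_mdp(rng, 3, 3)
        model = model_from(probs, rewards)
        behavior = TabularPolicy.uniform(3, 3)
        policy = clinician_policy(model, behavior, 0.0)
        np.testing.assert_array_equal(policy.actions(), rewards.argmax(axis=1))

    def test_clinician_fixed_point_when_behavior_greedy(self):
        """If the behavior policy is already greedy with respect to its own
        value, one improvement cycle returns its argmax unchanged."""
        rng = np.random.default_rng(7)
        probs, rewards = random_mdp(rng, 3, 3)
        model = model_from(probs, rewards)
        optimal = policy_iteration(model, 0.3)
        again = clinician_policy(model, optimal, 0.3)
        np.testing.assert_array_equal(again.actions(), optimal.actions())

    def test_clinician_prefers_strictly_better_action(self):
        probs = np.ones((1, 2, 1))
        rewards = np.array([[0.0, 2.0]])
        model = model_from(probs, rewards)
        behavior = TabularPolicy(np.array([[0.3, 0.7]]))
        assert clinician_policy(model, behavior, 0.3).actions()[0] == 1


def test_policy_row_validation():
    with pytest.raises(DomainError):
        TabularPolicy(np.array([[0.5, 0.4]]))
    with pytest.raises(DomainError):
        TabularPolicy(np.array([[1.2, -0.2]]))
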