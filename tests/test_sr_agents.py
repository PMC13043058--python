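"""Tabular SR, deep successor features, policies and matrix extraction."""

import numpy as np
import pytest

from latentsr import sr_agents as sa
from latentsr.maze_env import InvalidSpecError, N_ACTIONS
from latentsr.state_features import FeatureMap, imagelike_features, onehot_features
from latentsr.sr_agents import (
    DSRAgent,
    ExperienceBuffer,
    PolicySpec,
    SuccessorFeatureModel,
    TabularSR,
    action_probabilities,
    compute_q,
    extract_deep_sr_matrix,
    reward_update,
    select_action,
    sf_update,
    solve_sr_matrix,
    sr_oracle_from_table,
    tabular_sr_oracle,
    tabular_sr_sweeps,
    tabular_sr_update,
    uniform_policy_table,
)

GAMMA = 0.9


# ---------------------------------------------------------------------------
# Tabular SR: TD rule and closed-form oracle
# ---------------------------------------------------------------------------


class TestTabularUpdate:
    def test_zero_step_size_is_identity(self):
        sr = TabularSR.zeros(4, gamma=GAMMA, alpha=0.0)
        before = sr.M.copy()
        tabular_sr_update(sr, (0, 1, 2), next_action=0)
        assert np.array_equal(sr.M, before)

    def test_single_full_step_writes_indicator(self):
        sr = TabularSR.zeros(4, gamma=GAMMA, alpha=1.0)
        tabular_sr_update(sr, (1, 2, 3), next_action=0)
        expected = np.zeros(4)
        expected[1] = 1.0
        assert np.array_equal(sr.M[1, :, 2], expected)
        # nothing else moved
        mask = np.ones_like(sr.M, dtype=bool)
        mask[1, :, 2] = False
        assert not sr.M[mask].any()

    def test_goal_self_update_fixed_point(self):
        # repeated self-transition at the goal converges to 1/(1-gamma)
        sr = TabularSR.zeros(2, gamma=GAMMA, alpha=0.5)
        for _ in range(400):
            tabular_sr_update(sr, (0, 0, 0), next_action=0)
        assert sr.M[0, 0, 0] == pytest.approx(1.0 / (1.0 - GAMMA), rel=1e-6)


class TestOracle:
    def test_two_state_cycle_closed_form(self):
        table = np.full((2, N_ACTIONS), -1, dtype=int)
        table[0, 1] = 1
        table[1, 1] = 0
        policy = np.zeros((2, N_ACTIONS))
        policy[:, 1] = 1.0
        _, V = sr_oracle_from_table(table, policy, gamma=0.5)
        assert np.allclose(V, [[4 / 3, 2 / 3], [2 / 3, 4 / 3]])

    def test_gamma_zero_rows_are_onehot(self, grid3):
        M = tabular_sr_oracle(grid3, uniform_policy_table(grid3), gamma=0.0)
        for s in range(9):
            for a in grid3.allowed_actions(s):
                expected = np.zeros(9)
                expected[s] = 1.0
                assert np.array_equal(M[s, :, a], expected)

    def test_corridor_goal_occupancy_geometric(self):
        # s0 -> s1 -> g with a goal self-loop: occupancy of g from s0 is
        # gamma^2 / (1 - gamma)
        table = np.full((3, N_ACTIONS), -1, dtype=int)
        table[0, 1] = 1
        table[1, 1] = 2
        table[2, 1] = 2  # absorbing self-loop
        policy = np.zeros((3, N_ACTIONS))
        policy[:, 1] = 1.0
        _, V = sr_oracle_from_table(table, policy, GAMMA)
        assert V[0, 2] == pytest.approx(GAMMA**2 / (1 - GAMMA))  # 8.1

    def test_unstable_discount_rejected(self, grid3):
        with pytest.raises(InvalidSpecError):
            tabular_sr_oracle(grid3, uniform_policy_table(grid3), gamma=1.0)

    def test_policy_mass_on_masked_action_rejected(self, grid3):
        bad = np.full((9, N_ACTIONS), 0.25)
        with pytest.raises(InvalidSpecError):
            tabular_sr_oracle(grid3, bad, GAMMA)


def test_td_trajectory_converges_on_deterministic_cycle():
    """On a deterministic cycle the sampled TD rule has no noise and
    converges to the exact Bellman solution."""
    table = np.full((3, N_ACTIONS), -1, dtype=int)
    for s in range(3):
        table[s, 1] = (s + 1) % 3
    policy = np.zeros((3, N_ACTIONS))
    policy[:, 1] = 1.0
    Mstar, _ = sr_oracle_from_table(table, policy, GAMMA)
    sr = TabularSR.zeros(3, gamma=GAMMA, alpha=0.3)
    s = 0
    for _ in range(3000):
        s2 = table[s, 1]
        tabular_sr_update(sr, (s, 1, s2), next_action=1)
        s = s2
    allowed = table >= 0
    assert np.max(np.abs(sr.M[:, :, 1] - Mstar[:, :, 1])) < 1e-6


def test_expected_sweeps_match_oracle(grid3):
    policy = uniform_policy_table(grid3)
    Mstar = tabular_sr_oracle(grid3, policy, GAMMA)
    sr = tabular_sr_sweeps(grid3, policy, GAMMA, n_sweeps=150)
    assert np.max(np.abs(sr.M - Mstar)) < 1e-3


# ---------------------------------------------------------------------------
# Deep successor features
# ---------------------------------------------------------------------------


def _stream(env, rng, n, doors=False):
    """Random-walk experience stream as per-step singleton batches."""
    s = env.start
    out = []
    for _ in range(n):
        a = int(rng.choice(env.allowed_actions(s, doors)))
        s2 = env.next_state(s, a, doors)
        out.append((s, a, s2, 0.0))
        s = s2
    return out


class TestSFUpdate:
    def test_zero_learning_rate_is_identity(self, grid3):
        feats = onehot_features(grid3)
        model = SuccessorFeatureModel(feats, lr_sf=0.0, lr_reward=0.0, seed=1)
        before = model.W.copy()
        batch = (np.array([0]), np.array([1]), np.array([1]), np.zeros(1))
        sf_update(model, batch)
        assert np.array_equal(model.W, before)

    def test_matches_tabular_on_shared_stream(self, grid10, grid10_onehot, rng):
        """With one-hot features and a linear map, the deep update is the
        tabular TD rule; both learners see the identical stream."""
        alpha = 0.07
        model = SuccessorFeatureModel(
            grid10_onehot, gamma=GAMMA, lr_sf=alpha, lr_reward=0.0, init="zeros"
        )
        tab = TabularSR.zeros(grid10.n_states, gamma=GAMMA, alpha=alpha)
        mask = grid10.transition_table(False) >= 0
        for s, a, s2, r in _stream(grid10, rng, 2500):
            q2 = model.q_values(np.array([s2]))[0]
            a_star = int(np.argmax(np.where(mask[s2], q2, -np.inf)))
            tabular_sr_update(tab, (s, a, s2), a_star)
            sf_update(
                model,
                (np.array([s]), np.array([a]), np.array([s2]), np.array([r])),
                allowed_mask=mask,
            )
        for a in range(N_ACTIONS):
            C = extract_deep_sr_matrix(model, grid10_onehot, a)
            assert np.max(np.abs(C - tab.M[:, :, a])) < 1e-6

    def test_goal_self_training_reaches_discounted_fixed_point(self, grid3):
        feats = onehot_features(grid3)
        model = SuccessorFeatureModel(feats, gamma=GAMMA, lr_sf=0.5, init="zeros")
        g = grid3.goal
        batch = (
            np.full(N_ACTIONS, g),
            np.arange(N_ACTIONS),
            np.full(N_ACTIONS, g),
            np.zeros(N_ACTIONS),
        )
        for _ in range(300):
            sf_update(model, batch)
        target = feats.vector(g) / (1 - GAMMA)
        for a in range(N_ACTIONS):
            assert np.allclose(model.sf_states(np.array([g]), a)[0], target, atol=1e-4)

    def test_zero_vector_goal_ablation_suppresses_goal_row(self, grid3):
        feats = onehot_features(grid3)
        model = SuccessorFeatureModel(feats, gamma=GAMMA, lr_sf=0.5, init="zeros")
        g = grid3.goal
        batch = (
            np.full(N_ACTIONS, g),
            np.arange(N_ACTIONS),
            np.full(N_ACTIONS, g),
            np.zeros(N_ACTIONS),
        )
        for _ in range(100):
            sf_update(model, batch, zero_target_states={g})
        assert np.allclose(model.W[:, g, :], 0.0)


class TestRewardUpdate:
    def test_zero_rewards_keep_zero_weights(self, grid3):
        model = SuccessorFeatureModel(onehot_features(grid3), init="zeros")
        batch = (np.array([0, 1]), np.array([1, 1]), np.array([1, 2]), np.zeros(2))
        reward_update(model, batch)
        assert not model.w.any()

    def test_goal_arrivals_fit_reward(self, grid3):
        model = SuccessorFeatureModel(
            onehot_features(grid3), lr_reward=0.2, init="zeros"
        )
        g = grid3.goal
        batch = (np.array([1]), np.array([1]), np.array([g]), np.array([5.0]))
        for _ in range(200):
            reward_update(model, batch)
        assert model.w[g] == pytest.approx(5.0, rel=1e-4)
        others = np.delete(model.w, g)
        assert np.allclose(others, 0.0)


def test_q_decomposition_equals_tabular_form(grid3, rng):
    """With one-hot features, m(s,a).w equals sum_s' M(s,s',a) R(s')."""
    feats = onehot_features(grid3)
    model = SuccessorFeatureModel(feats, seed=5)
    R = rng.normal(size=grid3.n_states)
    model.w = R.copy()
    for s in range(grid3.n_states):
        q = compute_q(model, s)
        for a in range(N_ACTIONS):
            M_row = extract_deep_sr_matrix(model, feats, a)[s]
            assert q[a] == pytest.approx(float(M_row @ R), abs=1e-10)


def test_corridor_q_value_product():
    # converged corridor SR times w = 5 e_g gives Q(s0, right) = 8.1 * 5
    table = np.full((3, N_ACTIONS), -1, dtype=int)
    table[0, 1] = 1
    table[1, 1] = 2
    table[2, 1] = 2
    policy = np.zeros((3, N_ACTIONS))
    policy[:, 1] = 1.0
    M, _ = sr_oracle_from_table(table, policy, GAMMA)
    w = 5.0 * np.eye(3)[2]
    assert M[0, :, 1] @ w == pytest.approx(40.5)


# ---------------------------------------------------------------------------
# Action selection
# ---------------------------------------------------------------------------


class TestSelectAction:
    def test_single_allowed_action_is_forced(self, rng):
        a = select_action(PolicySpec(), np.zeros(4), np.array([2]), rng)
        assert a == 2

    def test_softmax_zero_temperature_uniform(self):
        probs = action_probabilities(
            PolicySpec(kind="softmax", beta=0.0), np.array([9.0, -4.0, 2.0, 0.0]), np.arange(4)
        )
        assert np.allclose(probs, 0.25)

    def test_softmax_logistic_closed_form(self):
        probs = action_probabilities(
            PolicySpec(kind="softmax", beta=1.0), np.array([1.0, 0.0]), np.arange(2)
        )
        assert np.allclose(probs, [0.7311, 0.2689], atol=1e-4)

    @pytest.mark.parametrize(
        "policy,q",
        [
            (PolicySpec(kind="epsilon-greedy", epsilon=0.3), np.array([0.5, 0.1, 0.4, 0.2])),
            (PolicySpec(kind="epsilon-greedy", epsilon=0.3), np.array([0.5, 0.5, 0.1, 0.1])),
            (PolicySpec(kind="softmax", beta=1.0), np.array([1.0, 0.0, -1.0, 0.5])),
        ],
    )
    def test_empirical_frequencies_match_probabilities(self, policy, q, rng):
        allowed = np.array([0, 1, 3])
        probs = action_probabilities(policy, q, allowed)
        n = 100_000
        draws = np.array([select_action(policy, q, allowed, rng) for _ in range(n)])
        for a, p in zip(allowed, probs):
            freq = np.mean(draws == a)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * max(se, 1e-4)

    def test_probabilities_sum_to_one_and_masked_zero(self):
        probs = action_probabilities(PolicySpec(), np.arange(4.0), np.array([1, 2]))
        assert probs.sum() == pytest.approx(1.0)
        assert probs.size == 2  # masked actions carry no mass


# ---------------------------------------------------------------------------
# Deep-SR matrix extraction
# ---------------------------------------------------------------------------


class TestExtraction:
    def test_identity_features_return_sf_matrix(self, grid3):
        feats = onehot_features(grid3)
        model = SuccessorFeatureModel(feats, seed=2)
        for a in range(N_ACTIONS):
            assert np.allclose(
                extract_deep_sr_matrix(model, feats, a), model.W[a], atol=1e-12
            )

    def test_scaled_identity_divides_out(self, grid3):
        feats = FeatureMap(matrix=2.0 * np.eye(9), kind="image-like", seed=0)
        model = SuccessorFeatureModel(feats, seed=2)
        C = extract_deep_sr_matrix(model, feats, 0)
        assert np.allclose(C, feats.matrix @ model.W[0] / 2.0)

    def test_planted_occupancy_recovery(self, grid10, rng):
        feats = imagelike_features(grid10, D=256, seed=11)
        C0 = rng.random((100, 100))
        M_phi = C0 @ feats.matrix
        C = solve_sr_matrix(M_phi, feats)
        assert np.max(np.abs(C - C0)) < 1e-6


# ---------------------------------------------------------------------------
# Buffer and agent-level behavior
# ---------------------------------------------------------------------------


def test_buffer_sampling_is_uniform(rng):
    buf = ExperienceBuffer()
    for i in range(10):
        buf.append(i, 0, i, 0.0)
    s, _, _, _ = buf.sample(50_000, rng)
    freqs = np.bincount(s, minlength=10) / 50_000
    assert np.all(np.abs(freqs - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 50_000))


def test_buffer_never_evicts():
    buf = ExperienceBuffer(capacity=2)
    for i in range(100):
        buf.append(i, 1, i + 1, 0.5)
    assert len(buf) == 100
    s, a, s2, r = buf.tuples()
    assert s[0] == 0 and s2[-1] == 100


def test_goal_injection_appends_one_tuple_per_action(grid3):
    buf = ExperienceBuffer()
    injected = sa.goal_replay_injection(buf, terminal_state=grid3.goal, reward=0.0)
    assert len(buf) == N_ACTIONS and len(injected) == N_ACTIONS
    s, a, s2, r = buf.tuples()
    assert np.all(s == grid3.goal) and np.all(s2 == grid3.goal) and not r.any()
    assert sorted(a.tolist()) == list(range(N_ACTIONS))


def test_agent_seed_determinism(grid3):
    feats = onehot_features(grid3)

    def run(seed):
        agent = DSRAgent(grid3, feats, PolicySpec(), seed=seed)
        agent.set_phase(False, terminal_state=grid3.goal)
        s = grid3.start
        for _ in range(300):
            a = agent.act(s)
            s2 = grid3.next_state(s, a)
            agent.observe(s, a, s2, float(s2 == grid3.goal))
            s = s2
        return agent.model.W.copy(), agent.model.w.copy()

    W1, w1 = run(9)
    W2, w2 = run(9)
    W3, _ = run(10)
    assert np.array_equal(W1, W2) and np.array_equal(w1, w2)
    assert not np.array_equal(W1, W3)


def test_onehot_occupancy_stays_bounded(grid3):
    feats = onehot_features(grid3)
    agent = DSRAgent(grid3, feats, PolicySpec(), seed=0, lr_sf=0.1)
    agent.set_phase(False, terminal_state=grid3.goal)
    rng = np.random.default_rng(1)
    s = grid3.start
    for _ in range(4000):
        a = agent.act(s)
        s2 = grid3.next_state(s, a)
        agent.observe(s, a, s2, 0.0)
        if s2 == grid3.goal:
            agent.inject_terminal_self(grid3.goal, 0.0)
            s = grid3.start
        else:
            s = s2
    delta = 0.05
    mask = grid3.transition_table(False) >= 0
    for a in range(N_ACTIONS):
        C = extract_deep_sr_matrix(agent.model, feats, a)
        # masked state-action pairs are never trained and keep their
        # initialization; the occupancy bound applies to trained rows
        trained = mask[:, a].copy()
        trained[grid3.goal] = True
        assert C[trained].min() > -delta
        assert C[trained].max() < 1.0 / (1.0 - agent.model.gamma) + delta
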