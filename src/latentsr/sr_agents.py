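"""Successor-representation learners.

Two implementations of the same object live here. ``TabularSR`` stores
the action-conditioned successor matrix ``M(s, s', a)`` — the expected
discounted number of future visits to ``s'`` after taking ``a`` in
``s`` — updated by a temporal-difference rule, with a closed-form
Bellman solve as an oracle. ``SuccessorFeatureModel`` is the deep
variant: one linear map per action sends a state feature ``phi(s)`` to
its successor-feature vector ``m(s, a)``, and a separate linear head
``w`` (no bias) predicts reward from features, so that
``Q(s, a) = m(s, a) . w``. With one-hot features the two coincide
exactly, which the tests exploit.

Learning is replay-based: every experienced ``(s, a, s', r)`` tuple is
stored in an append-only buffer and sampled uniformly. For designs whose
trials end at a terminal landmark, self-transitions at that landmark are
additionally injected and replayed, which anchors and amplifies the
landmark's successor feature (``m(g, a) -> phi(g) / (1 - gamma)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .maze_env import (
    ContractViolationError,
    EnvironmentSpec,
    InvalidSpecError,
    N_ACTIONS,
)
from .state_features import DegenerateFeaturesError, FeatureMap

# ---------------------------------------------------------------------------
# Tabular SR
# ---------------------------------------------------------------------------


@dataclass
class TabularSR:
    """Action-conditioned successor matrix with TD learning parameters."""

    M: np.ndarray  # (N, N, A)
    gamma: float
    alpha: float

    @classmethod
    def zeros(cls, n_states: int, gamma: float = 0.9, alpha: float = 0.1) -> "TabularSR":
        return cls(M=np.zeros((n_states, n_states, N_ACTIONS)), gamma=gamma, alpha=alpha)


def tabular_sr_update(
    sr: TabularSR, transition: tuple[int, int, int], next_action: int
) -> TabularSR:
    """One TD update of the successor matrix for an observed transition.

    ``M(s, ., a) += alpha * [ e_s + gamma * M(s', ., a') - M(s, ., a) ]``
    where ``a'`` is the action chosen at ``s'`` by the running policy.
    """
    s, a, s2 = transition
    row = sr.M[s, :, a]
    target = sr.gamma * sr.M[s2, :, next_action].copy()
    target[s] += 1.0
    row += sr.alpha * (target - row)
    return sr


def tabular_sr_sweeps(
    env: EnvironmentSpec,
    policy_probs: np.ndarray,
    gamma: float,
    n_sweeps: int = 200,
    alpha: float = 1.0,
    doors_enabled: bool = False,
    sr: Optional[TabularSR] = None,
) -> TabularSR:
    """Learn the SR by sweeping the TD rule in expectation over all
    state-action pairs under a frozen policy.

    Each sweep applies ``M(s,.,a) += alpha [ e_s + gamma E_pi M(s',.,a')
    - M(s,.,a) ]`` synchronously for every allowed pair; with
    ``alpha = 1`` this is exact policy evaluation and the error contracts
    by ``gamma`` per sweep toward the Bellman fixed point.
    """
    table = env.transition_table(doors_enabled)
    n = env.n_states
    if sr is None:
        sr = TabularSR.zeros(n, gamma=gamma, alpha=alpha)
    policy_probs = np.asarray(policy_probs, dtype=float)
    eye = np.eye(n)
    allowed_pairs = [(s, a) for s in range(n) for a in range(N_ACTIONS) if table[s, a] >= 0]
    for _ in range(n_sweeps):
        # expected successor row under the policy, per state
        em = np.einsum("sa,sna->sn", policy_probs, sr.M)
        new = sr.M.copy()
        for s, a in allowed_pairs:
            target = eye[s] + gamma * em[table[s, a]]
            new[s, :, a] += alpha * (target - sr.M[s, :, a])
        sr.M = new
    return sr


def sr_oracle_from_table(
    table: np.ndarray, policy_probs: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form SR for a deterministic transition table and fixed policy.

    Solves the Bellman system exactly: with ``P(s, s') = sum_a pi(a|s)
    I[T(s,a)=s']``, the state-level occupancy is ``V = (I - gamma P)^-1``
    and ``M(s, ., a) = e_s + gamma V(T(s,a), .)`` for allowed actions
    (masked actions are left at zero).

    Returns ``(M, V)``.
    """
    if not 0.0 <= gamma < 1.0:
        raise InvalidSpecError("oracle requires 0 <= gamma < 1")
    n, n_a = table.shape
    policy_probs = np.asarray(policy_probs, dtype=float)
    if policy_probs.shape != (n, n_a):
        raise InvalidSpecError("policy table must be (N, A)")
    if np.any((table < 0) & (policy_probs > 0)):
        raise InvalidSpecError("policy puts mass on masked actions")
    if not np.allclose(policy_probs.sum(axis=1), 1.0):
        raise InvalidSpecError("policy rows must sum to 1")
    P = np.zeros((n, n))
    for s in range(n):
        for a in range(n_a):
            if policy_probs[s, a] > 0:
                P[s, table[s, a]] += policy_probs[s, a]
    V = np.linalg.inv(np.eye(n) - gamma * P)
    M = np.zeros((n, n, n_a))
    for s in range(n):
        for a in range(n_a):
            if table[s, a] >= 0:
                M[s, :, a] = gamma * V[table[s, a]]
                M[s, s, a] += 1.0
    return M, V


def tabular_sr_oracle(
    env: EnvironmentSpec,
    policy_probs: np.ndarray,
    gamma: float,
    doors_enabled: bool = False,
) -> np.ndarray:
    """Converged SR under a fixed stationary policy, by exact linear solve."""
    M, _ = sr_oracle_from_table(env.transition_table(doors_enabled), policy_probs, gamma)
    return M


def uniform_policy_table(env: EnvironmentSpec, doors_enabled: bool = False) -> np.ndarray:
    """Uniform-random policy over allowed actions, as an (N, A) table."""
    probs = np.zeros((env.n_states, N_ACTIONS))
    for s in range(env.n_states):
        allowed = env.allowed_actions(s, doors_enabled)
        probs[s, allowed] = 1.0 / allowed.size
    return probs


# ---------------------------------------------------------------------------
# Experience replay
# ---------------------------------------------------------------------------


class ExperienceBuffer:
    """Append-only store of (state, action, next state, reward) tuples
    with uniform random sampling. Nothing is ever evicted within a run."""

    def __init__(self, capacity: int = 1024) -> None:
        self._s = np.empty(capacity, dtype=np.int64)
        self._a = np.empty(capacity, dtype=np.int64)
        self._s2 = np.empty(capacity, dtype=np.int64)
        self._r = np.empty(capacity, dtype=np.float64)
        self._n = 0

    def __len__(self) -> int:
        return self._n

    def _grow(self) -> None:
        cap = 2 * self._s.size
        for name in ("_s", "_a", "_s2", "_r"):
            arr = getattr(self, name)
            new = np.empty(cap, dtype=arr.dtype)
            new[: self._n] = arr[: self._n]
            setattr(self, name, new)

    def append(self, s: int, a: int, s2: int, r: float) -> None:
        if self._n == self._s.size:
            self._grow()
        i = self._n
        self._s[i], self._a[i], self._s2[i], self._r[i] = s, a, s2, r
        self._n += 1

    def sample(
        self, batch_size: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if self._n == 0:
            raise ContractViolationError("cannot sample from an empty buffer")
        idx = rng.integers(0, self._n, size=batch_size)
        return self._s[idx], self._a[idx], self._s2[idx], self._r[idx]

    def tuples(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        n = self._n
        return self._s[:n], self._a[:n], self._s2[:n], self._r[:n]


# ---------------------------------------------------------------------------
# Action selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolicySpec:
    """Exploration policy: epsilon-greedy or softmax over allowed actions."""

    kind: str = "epsilon-greedy"
    epsilon: float = 0.3
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("epsilon-greedy", "softmax"):
            raise InvalidSpecError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise InvalidSpecError("epsilon must lie in [0, 1]")
        if self.beta < 0.0:
            raise InvalidSpecError("beta must be non-negative")


def action_probabilities(
    policy: PolicySpec, q_values: np.ndarray, allowed: np.ndarray
) -> np.ndarray:
    """Selection probabilities over ``allowed`` (same order), summing to 1.

    Epsilon-greedy splits the greedy mass uniformly over exactly tied
    maxima; softmax uses ``p(a) proportional to exp(beta q(a))``.
    """
    qa = np.asarray(q_values, dtype=float)[allowed]
    k = allowed.size
    if policy.kind == "epsilon-greedy":
        probs = np.full(k, policy.epsilon / k)
        best = np.flatnonzero(qa == qa.max())
        probs[best] += (1.0 - policy.epsilon) / best.size
        return probs
    z = policy.beta * qa
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def select_action(
    policy: PolicySpec,
    q_values: np.ndarray,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Draw one action from the policy distribution over allowed actions."""
    if allowed.size == 0:
        raise ContractViolationError("allowed action set is empty")
    if allowed.size == 1:
        return int(allowed[0])
    qa = np.asarray(q_values, dtype=float)[allowed]
    if policy.kind == "epsilon-greedy":
        if rng.random() < policy.epsilon:
            return int(allowed[rng.integers(allowed.size)])
        best = np.flatnonzero(qa == qa.max())
        return int(allowed[best[rng.integers(best.size)]])
    z = policy.beta * qa
    z -= z.max()
    p = np.exp(z)
    c = np.cumsum(p)
    return int(allowed[np.searchsorted(c, rng.random() * c[-1], side="right")])


# ---------------------------------------------------------------------------
# Deep successor-feature model
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class SuccessorFeatureModel:
    """Per-action successor-feature maps plus a linear reward head.

    The default architecture is a single linear layer per action with no
    bias, ``m(s, a) = phi(s) W_a``, which makes the model exactly
    equivalent to the tabular SR when features are one-hot and allows
    the occupancy matrix to be read out by least squares. An optional
    one-hidden-layer ReLU variant is available for image-like features.

    Parameters
    ----------
    features
        The state feature map; its dimension fixes the layer sizes.
    gamma
        Discount factor for the successor accumulation.
    lr_sf, lr_reward
        SGD step sizes for the SF maps and the reward head. Gradients are
        summed (not averaged) over a batch, so with one-hot features
        ``lr_sf`` plays the role of the tabular learning rate ``alpha``.
    init
        ``"glorot"`` (default) or ``"zeros"``.
    hidden
        If a positive integer, use a one-hidden-layer ReLU map of that
        width per action instead of the linear map.
    """

    def __init__(
        self,
        features: FeatureMap,
        gamma: float = 0.9,
        lr_sf: float = 0.05,
        lr_reward: float = 0.2,
        init: str = "glorot",
        seed: int = 0,
        hidden: int = 0,
    ) -> None:
        self.features = features
        self.gamma = float(gamma)
        self.lr_sf = float(lr_sf)
        self.lr_reward = float(lr_reward)
        self.hidden = int(hidden)
        d = features.n_features
        rng = np.random.default_rng(seed)
        if init not in ("glorot", "zeros"):
            raise InvalidSpecError(f"unknown init {init!r}")
        if self.hidden > 0:
            h = self.hidden
            make = _glorot if init == "glorot" else (lambda r, sh: np.zeros(sh))
            self.W1 = np.stack([make(rng, (d, h)) for _ in range(N_ACTIONS)])
            self.W2 = np.stack([make(rng, (h, d)) for _ in range(N_ACTIONS)])
            self.W = None
        else:
            if init == "glorot":
                self.W = np.stack([_glorot(rng, (d, d)) for _ in range(N_ACTIONS)])
            else:
                self.W = np.zeros((N_ACTIONS, d, d))
        if init == "glorot":
            self.w = _glorot(rng, (d, 1))[:, 0]
        else:
            self.w = np.zeros(d)

    # -- forward passes --------------------------------------------------

    def sf(self, phi: np.ndarray, action: int) -> np.ndarray:
        """Successor-feature vector(s) for feature input(s) under one action."""
        if self.hidden > 0:
            return np.maximum(phi @ self.W1[action], 0.0) @ self.W2[action]
        return phi @ self.W[action]

    @property
    def _onehot_linear(self) -> bool:
        return self.hidden == 0 and self.features.kind == "onehot"

    def sf_states(self, states: np.ndarray, action: int) -> np.ndarray:
        """SF vectors for a batch of state indices (row gather when one-hot)."""
        if self._onehot_linear:
            return self.W[action][states]
        return self.sf(self.features.matrix[states], action)

    def sf_matrix(self, action: int) -> np.ndarray:
        """SF vectors of all states stacked into an (N, D) matrix."""
        return self.sf(self.features.matrix, action)

    def q_all_states(self) -> np.ndarray:
        """Q(s, a) for every state and action, shape (N, A)."""
        phi = self.features.matrix
        out = np.empty((phi.shape[0], N_ACTIONS))
        for a in range(N_ACTIONS):
            if self.hidden > 0:
                out[:, a] = self.sf(phi, a) @ self.w
            else:
                out[:, a] = phi @ (self.W[a] @ self.w)
        return out

    def q_values(self, states: np.ndarray) -> np.ndarray:
        """Q(s, a) for a batch of state indices, shape (B, A)."""
        out = np.empty((states.shape[0], N_ACTIONS))
        if self._onehot_linear:
            for a in range(N_ACTIONS):
                out[:, a] = self.W[a][states] @ self.w
            return out
        phi = self.features.matrix[states]
        for a in range(N_ACTIONS):
            if self.hidden > 0:
                out[:, a] = self.sf(phi, a) @ self.w
            else:
                out[:, a] = phi @ (self.W[a] @ self.w)
        return out


def compute_q(model: SuccessorFeatureModel, state: int) -> np.ndarray:
    """Per-action values ``Q(s, a) = m(s, a) . w`` for one state."""
    return model.q_values(np.array([state]))[0]


def duplicate_clip_weights(keys: np.ndarray, lr: float, cap: float = 1.0) -> np.ndarray:
    """Per-sample scale factors keeping the effective TD step contractive.

    Gradients are summed over a batch, so ``k`` samples updating the same
    table row move it by ``lr * k`` times the mean error; for
    ``lr * k > 2`` that fixed-point iteration diverges (small buffers and
    door-pocket dwelling make such duplicate pile-ups common). Samples in
    an over-represented group are scaled so the group's total step is
    ``min(lr * k, cap)``; groups with ``lr * k <= cap`` are untouched.
    """
    if lr <= 0.0:
        return np.ones(len(keys))
    _, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)
    k = counts[inverse]
    return np.minimum(1.0, cap / (lr * k))


def _gram_step_clip(phi_batch: np.ndarray, lr: float, cap: float = 1.0) -> float:
    """Scalar step scale keeping a summed least-squares step contractive.

    For correlated (image-like) feature rows the summed-gradient step is
    stable only if ``lr`` times the batch Gram's largest eigenvalue stays
    below 2; the step is scaled so it never exceeds ``cap``.
    """
    lam = float(np.linalg.eigvalsh(phi_batch @ phi_batch.T)[-1])
    if lr * lam <= cap:
        return 1.0
    return cap / (lr * lam)


def _sf_update_onehot_linear(
    model: SuccessorFeatureModel,
    s: np.ndarray,
    a: np.ndarray,
    s2: np.ndarray,
    allowed_mask: Optional[np.ndarray],
    bootstrap_actions: Optional[np.ndarray],
    zero_target_states: Optional[set[int]],
) -> SuccessorFeatureModel:
    """Row-gather/scatter form of :func:`sf_update` for one-hot features;
    numerically identical to the general path."""
    W = model.W
    if bootstrap_actions is None:
        q2 = W[:, s2, :] @ model.w  # (A, B)
        if allowed_mask is not None:
            q2 = np.where(allowed_mask[s2].T, q2, -np.inf)
        bootstrap_actions = np.argmax(q2, axis=0)
    targets = model.gamma * W[bootstrap_actions, s2]  # (B, D)
    targets[np.arange(s.size), s] += 1.0
    if zero_target_states:
        targets[np.isin(s, list(zero_target_states))] = 0.0
    delta = targets - W[a, s]
    scale = duplicate_clip_weights(a * W.shape[1] + s, model.lr_sf)
    np.add.at(W, (a, s), model.lr_sf * (scale[:, None] * delta))
    return model


def sf_update(
    model: SuccessorFeatureModel,
    batch: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    allowed_mask: Optional[np.ndarray] = None,
    bootstrap_actions: Optional[np.ndarray] = None,
    zero_target_states: Optional[set[int]] = None,
) -> SuccessorFeatureModel:
    """One SGD step of the SF maps toward their TD targets.

    The target for tuple ``(s, a, s', .)`` is
    ``phi(s) + gamma * m(s', a*)``, held fixed within the step. The
    bootstrap action ``a*`` is the greedy action at ``s'`` (restricted
    to ``allowed_mask`` when given) unless explicit ``bootstrap_actions``
    are supplied. States in ``zero_target_states`` are regressed to the
    zero vector instead (ablation).
    """
    s, a, s2, _ = batch
    phi = model.features.matrix
    onehot = model._onehot_linear
    if onehot:
        return _sf_update_onehot_linear(
            model, s, a, s2, allowed_mask, bootstrap_actions, zero_target_states
        )
    if bootstrap_actions is None:
        q2 = model.q_values(s2)
        if allowed_mask is not None:
            q2 = np.where(allowed_mask[s2], q2, -np.inf)
        bootstrap_actions = np.argmax(q2, axis=1)
    # targets, from pre-update parameters
    m2 = np.empty((s.size, phi.shape[1]))
    for act in range(N_ACTIONS):
        rows = np.flatnonzero(bootstrap_actions == act)
        if rows.size:
            m2[rows] = model.sf_states(s2[rows], act)
    targets = model.gamma * m2
    if onehot:
        targets[np.arange(s.size), s] += 1.0
    else:
        targets += phi[s]
    if zero_target_states:
        mask = np.isin(s, list(zero_target_states))
        targets[mask] = 0.0
    for act in range(N_ACTIONS):
        rows = np.flatnonzero(a == act)
        if rows.size == 0:
            continue
        delta = targets[rows] - model.sf_states(s[rows], act)
        delta = _gram_step_clip(phi[s[rows]], model.lr_sf) * delta
        if model.hidden > 0:
            x = phi[s[rows]]
            pre = x @ model.W1[act]
            hid = np.maximum(pre, 0.0)
            g2 = hid.T @ delta
            g1 = x.T @ ((delta @ model.W2[act].T) * (pre > 0))
            model.W1[act] += model.lr_sf * g1
            model.W2[act] += model.lr_sf * g2
        elif onehot:
            np.add.at(model.W[act], s[rows], model.lr_sf * delta)
        else:
            model.W[act] += model.lr_sf * (phi[s[rows]].T @ delta)
    return model


def reward_update(
    model: SuccessorFeatureModel,
    batch: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
) -> SuccessorFeatureModel:
    """One SGD step of the reward head toward observed rewards.

    Regresses ``phi(s') . w`` onto the reward received on arriving at
    ``s'``; gradients are summed over the batch, with over-represented
    arrival states step-clipped to keep the iteration stable.
    """
    _, _, s2, r = batch
    if model._onehot_linear:
        scale = duplicate_clip_weights(s2, model.lr_reward)
        delta = r - model.w[s2]
        np.add.at(model.w, s2, model.lr_reward * (scale * delta))
        return model
    phi2 = model.features.matrix[s2]
    delta = _gram_step_clip(phi2, model.lr_reward) * (r - phi2 @ model.w)
    model.w += model.lr_reward * (phi2.T @ delta)
    return model


def goal_replay_injection(
    buffer: ExperienceBuffer,
    terminal_state: int,
    reward: float,
) -> list[tuple[int, int, int, float]]:
    """Append one self-transition per action at a trial's terminal state.

    Models the post-trial confinement at the goal cage: tuples
    ``(g, a, g, r)`` for every action, with the phase's reward at the
    goal (zero during pre-exposure). Returns the injected tuples so the
    caller can replay them explicitly.
    """
    injected = []
    for a in range(N_ACTIONS):
        buffer.append(terminal_state, a, terminal_state, reward)
        injected.append((terminal_state, a, terminal_state, reward))
    return injected


def extract_deep_sr_matrix(
    model: SuccessorFeatureModel, features: FeatureMap, action: int
) -> np.ndarray:
    """Recover the state-to-state occupancy matrix ``C^a`` from the SF map.

    Solves the least-squares problem ``M_Phi^a = C^a Phi`` using the
    state-feature Gram matrix; row ``i`` of ``C^a`` estimates the
    expected discounted visitation frequencies from state ``i``. With
    one-hot features this returns the SF matrix itself.
    """
    m_phi = model.sf(features.matrix, action)
    gram = features.gram()
    try:
        sol = np.linalg.solve(gram, features.matrix @ m_phi.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFeaturesError(f"feature Gram matrix is singular: {exc}") from exc
    return sol.T


def solve_sr_matrix(m_phi: np.ndarray, features: FeatureMap) -> np.ndarray:
    """Least-squares occupancy extraction for an explicit SF matrix."""
    gram = features.gram()
    try:
        sol = np.linalg.solve(gram, features.matrix @ m_phi.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFeaturesError(f"feature Gram matrix is singular: {exc}") from exc
    return sol.T


# ---------------------------------------------------------------------------
# Agent wrapper used by the experiment protocols
# ---------------------------------------------------------------------------


class DSRAgent:
    """Deep successor-representation agent with uniform replay.

    Binds a :class:`SuccessorFeatureModel`, an :class:`ExperienceBuffer`
    and a :class:`PolicySpec` into the step-level interface the
    protocols drive: act, observe (store + one replay batch), and
    terminal self-transition injection.
    """

    kind = "dsr"

    def __init__(
        self,
        env: EnvironmentSpec,
        features: FeatureMap,
        policy: PolicySpec,
        seed: int = 0,
        gamma: float = 0.9,
        lr_sf: float = 0.05,
        lr_reward: float = 0.2,
        batch_size: int = 32,
        init: str = "glorot",
        hidden: int = 0,
        bootstrap: str = "greedy",
        goal_replay: bool = True,
        n_goal_replays: int = 1,
        zero_vector_goal: bool = False,
        buffer_filter_state: Optional[int] = None,
    ) -> None:
        self.env = env
        self.features = features
        self.policy = policy
        self.rng = np.random.default_rng(seed)
        self.model = SuccessorFeatureModel(
            features,
            gamma=gamma,
            lr_sf=lr_sf,
            lr_reward=lr_reward,
            init=init,
            seed=int(np.random.default_rng(seed + 1).integers(2**31)),
            hidden=hidden,
        )
        self.buffer = ExperienceBuffer()
        self.batch_size = int(batch_size)
        if bootstrap not in ("greedy", "policy"):
            raise InvalidSpecError(f"unknown bootstrap mode {bootstrap!r}")
        self.bootstrap = bootstrap
        self.goal_replay = bool(goal_replay)
        self.n_goal_replays = int(n_goal_replays)
        self.zero_vector_goal = bool(zero_vector_goal)
        self.buffer_filter_state = buffer_filter_state
        self._doors_enabled = False
        self._allowed_mask = env.transition_table(False) >= 0
        self._zero_targets: Optional[set[int]] = {env.goal} if zero_vector_goal else None

    def set_phase(self, doors_enabled: bool, terminal_state: Optional[int] = None) -> None:
        # terminal_state is part of the shared agent interface; the DSR
        # handles terminals through the goal self-loop, not a zero bootstrap
        self._doors_enabled = doors_enabled
        self._allowed_mask = self.env.transition_table(doors_enabled) >= 0

    def act(self, state: int) -> int:
        allowed = self.env.allowed_actions(state, self._doors_enabled)
        q = compute_q(self.model, state)
        return select_action(self.policy, q, allowed, self.rng)

    def observe(self, s: int, a: int, s2: int, r: float) -> None:
        if self.buffer_filter_state is not None and (
            s == self.buffer_filter_state or s2 == self.buffer_filter_state
        ):
            return
        self.buffer.append(s, a, s2, r)
        self.replay_step()

    def _bootstrap_actions(self, s2: np.ndarray) -> Optional[np.ndarray]:
        if self.bootstrap == "greedy":
            return None  # sf_update computes the greedy argmax itself
        # strict on-policy variant: sample the running policy at s'
        actions = np.empty(s2.size, dtype=np.int64)
        q2 = self.model.q_values(s2)
        for i, s in enumerate(s2):
            allowed = self.env.allowed_actions(int(s), self._doors_enabled)
            actions[i] = select_action(self.policy, q2[i], allowed, self.rng)
        return actions

    def _update(self, batch) -> None:
        sf_update(
            self.model,
            batch,
            allowed_mask=self._allowed_mask,
            bootstrap_actions=self._bootstrap_actions(batch[2]),
            zero_target_states=self._zero_targets,
        )
        reward_update(self.model, batch)

    def replay_step(self) -> None:
        if len(self.buffer) == 0:
            return
        self._update(self.buffer.sample(self.batch_size, self.rng))

    def inject_terminal_self(self, terminal_state: int, reward: float) -> None:
        """Goal-to-goal replay at trial end (skipped when disabled).

        The injected self-transitions are replayed for a short block of
        update passes, emulating the confinement period at the goal cage.
        """
        if not self.goal_replay:
            return
        injected = goal_replay_injection(self.buffer, terminal_state, reward)
        s, a, s2, r = (np.array(x) for x in zip(*injected))
        batch = (s, a, s2, r.astype(float))
        for _ in range(self.n_goal_replays):
            self._update(batch)

    def greedy_actions(self) -> np.ndarray:
        """Current greedy action in every state (ties -> lowest index)."""
        q = self.model.q_all_states()
        q = np.where(self._allowed_mask, q, -np.inf)
        return np.argmax(q, axis=1)

    def snapshot(self) -> dict:
        """Copy of the learned parameters for later analysis."""
        return {
            "sf": np.stack([self.model.sf_matrix(a) for a in range(N_ACTIONS)]),
            "w": self.model.w.copy(),
        }
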