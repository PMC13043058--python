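"""Dyna-style deep Q-learning baseline.

A model-free comparison agent that shares the environments, policies,
replay buffer, step limits and seeding interface of the DSR agent but
learns action values directly: a single linear map (no bias) from the
state feature to per-action Q values, trained by Q-learning on batches
drawn uniformly from the buffer of remembered real transitions
(memory-as-model Dyna planning). Because its values collapse to zero
during unrewarded exploration, it serves as the control showing that
sensitivity to pre-exposure design is specific to the successor
representation.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .maze_env import EnvironmentSpec, N_ACTIONS
from .sr_agents import (
    ExperienceBuffer,
    PolicySpec,
    _glorot,
    _gram_step_clip,
    duplicate_clip_weights,
    select_action,
)
from .state_features import FeatureMap


class DynaQModel:
    """Linear Q map ``phi(s) -> Q(s, .)`` with Q-learning updates."""

    def __init__(
        self,
        features: FeatureMap,
        gamma: float = 0.9,
        lr: float = 0.05,
        init: str = "glorot",
        seed: int = 0,
    ) -> None:
        self.features = features
        self.gamma = float(gamma)
        self.lr = float(lr)
        d = features.n_features
        rng = np.random.default_rng(seed)
        self.Wq = _glorot(rng, (d, N_ACTIONS)) if init == "glorot" else np.zeros((d, N_ACTIONS))

    def q_values(self, states: np.ndarray) -> np.ndarray:
        if self.features.kind == "onehot":
            return self.Wq[states]
        return self.features.matrix[states] @ self.Wq

    def q_all_states(self) -> np.ndarray:
        return self.features.matrix @ self.Wq


def dyna_q_update(
    model: DynaQModel,
    batch: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    allowed_mask: Optional[np.ndarray] = None,
    terminal_state: Optional[int] = None,
    target_Wq: Optional[np.ndarray] = None,
) -> DynaQModel:
    """One Q-learning step toward ``r + gamma max_a' Q(s', a')``.

    Transitions arriving at ``terminal_state`` bootstrap from zero.
    Gradients are summed over the batch. When ``target_Wq`` is given the
    bootstrap values come from that (periodically frozen) parameter copy,
    as in deep Q-networks.
    """
    s, a, s2, r = batch
    if target_Wq is not None:
        if model.features.kind == "onehot":
            q2 = target_Wq[s2]
        else:
            q2 = model.features.matrix[s2] @ target_Wq
    else:
        q2 = model.q_values(s2)
    if allowed_mask is not None:
        q2 = np.where(allowed_mask[s2], q2, -np.inf)
    boot = q2.max(axis=1)
    if terminal_state is not None:
        boot = np.where(s2 == terminal_state, 0.0, boot)
    targets = r + model.gamma * boot
    pred = model.q_values(s)[np.arange(s.size), a]
    delta = targets - pred
    if model.features.kind == "onehot":
        delta = duplicate_clip_weights(s * N_ACTIONS + a, model.lr) * delta
        np.add.at(model.Wq, (s, a), model.lr * delta)
        return model
    phi_s = model.features.matrix[s]
    for act in range(N_ACTIONS):
        rows = np.flatnonzero(a == act)
        if rows.size:
            d = _gram_step_clip(phi_s[rows], model.lr) * delta[rows]
            model.Wq[:, act] += model.lr * (phi_s[rows].T @ d)
    return model


class DynaAgent:
    """Protocol-facing wrapper with the same interface as ``DSRAgent``."""

    kind = "dyna"

    def __init__(
        self,
        env: EnvironmentSpec,
        features: FeatureMap,
        policy: PolicySpec,
        seed: int = 0,
        gamma: float = 0.9,
        lr: float = 0.05,
        batch_size: int = 32,
        init: str = "glorot",
        goal_replay: bool = True,
        n_goal_replays: int = 1,
        target_sync_every: int = 200,
        buffer_filter_state: Optional[int] = None,
        **_ignored,
    ) -> None:
        self.env = env
        self.features = features
        self.policy = policy
        self.rng = np.random.default_rng(seed)
        self.model = DynaQModel(
            features,
            gamma=gamma,
            lr=lr,
            init=init,
            seed=int(np.random.default_rng(seed + 1).integers(2**31)),
        )
        self.buffer = ExperienceBuffer()
        self.batch_size = int(batch_size)
        self.goal_replay = bool(goal_replay)
        self.n_goal_replays = int(n_goal_replays)
        self.buffer_filter_state = buffer_filter_state
        self._doors_enabled = False
        self._allowed_mask = env.transition_table(False) >= 0
        self._terminal_state: Optional[int] = None
        self.target_sync_every = int(target_sync_every)
        self._target_Wq = self.model.Wq.copy() if self.target_sync_every > 0 else None
        self._updates_since_sync = 0

    def set_phase(self, doors_enabled: bool, terminal_state: Optional[int] = None) -> None:
        self._doors_enabled = doors_enabled
        self._allowed_mask = self.env.transition_table(doors_enabled) >= 0
        self._terminal_state = terminal_state

    def act(self, state: int) -> int:
        allowed = self.env.allowed_actions(state, self._doors_enabled)
        q = self.model.q_values(np.array([state]))[0]
        return select_action(self.policy, q, allowed, self.rng)

    def observe(self, s: int, a: int, s2: int, r: float) -> None:
        if self.buffer_filter_state is not None and (
            s == self.buffer_filter_state or s2 == self.buffer_filter_state
        ):
            return
        self.buffer.append(s, a, s2, r)
        # direct RL on the real transition (Dyna's model-free half) ...
        self._update(
            (np.array([s]), np.array([a]), np.array([s2]), np.array([float(r)]))
        )
        # ... plus one planning batch from remembered transitions
        self.replay_step()

    def _update(self, batch) -> None:
        dyna_q_update(
            self.model,
            batch,
            allowed_mask=self._allowed_mask,
            terminal_state=self._terminal_state,
            target_Wq=self._target_Wq,
        )
        if self._target_Wq is not None:
            self._updates_since_sync += 1
            if self._updates_since_sync >= self.target_sync_every:
                self._target_Wq = self.model.Wq.copy()
                self._updates_since_sync = 0

    def replay_step(self) -> None:
        if len(self.buffer) == 0:
            return
        self._update(self.buffer.sample(self.batch_size, self.rng))

    def inject_terminal_self(self, terminal_state: int, reward: float) -> None:
        if not self.goal_replay:
            return
        s = np.full(N_ACTIONS, terminal_state)
        a = np.arange(N_ACTIONS)
        r = np.full(N_ACTIONS, reward, dtype=float)
        for act in range(N_ACTIONS):
            self.buffer.append(terminal_state, act, terminal_state, reward)
        batch = (s, a, s.copy(), r)
        for _ in range(self.n_goal_replays):
            self._update(batch)

    def greedy_actions(self) -> np.ndarray:
        q = self.model.q_all_states()
        q = np.where(self._allowed_mask, q, -np.inf)
        return np.argmax(q, axis=1)

    def snapshot(self) -> dict:
        return {"q": self.q_table_copy()}

    def q_table_copy(self) -> np.ndarray:
        return self.model.q_all_states().copy()
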