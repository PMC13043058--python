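"""Experiment orchestration: task designs, two-phase trial loops,
door conditions and multi-seed batches.

Four designs are supported. *Direct* learning has no pre-exposure.
*Targeted* pre-exposure trials end, unrewarded, at the future goal.
*Continuous* pre-exposure trials last exactly the step limit and start
from locations scattered over the maze (including the goal). *Mistargeted*
pre-exposure trials end at a non-goal landmark. The subsequent learning
phase is identical for every design: start at ``s``, reward at ``g``,
trial ends at the goal or the step cap.

Trial indices are global: ``-pre_trials .. -1`` for pre-exposure and
``0 .. learn_trials-1`` for learning. Parameter snapshots are taken at
the start of the run, at the phase boundary (trial 0) and after the last
learning trial.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .baseline_dyna import DynaAgent
from .maze_env import (
    ContractViolationError,
    EnvironmentSpec,
    InvalidSpecError,
    PhaseContext,
    build_gridworld,
    build_tolman_maze,
    step,
)
from .sr_agents import DSRAgent, PolicySpec
from .state_features import FeatureMap, imagelike_features, onehot_features

DESIGN_NAMES = ("direct", "targeted", "continuous", "mistargeted")


@dataclass(frozen=True)
class DesignSpec:
    """A latent-learning task design.

    ``pre_reward`` is always 0 (the pre-exposure is unrewarded) and
    ``learn_reward`` is the goal reward during the learning phase.
    """

    name: str
    pre_trials: int = 50
    learn_trials: int = 50
    pre_reward: float = 0.0
    learn_reward: float = 5.0

    def __post_init__(self) -> None:
        if self.name not in DESIGN_NAMES:
            raise InvalidSpecError(f"unknown design {self.name!r}")
        if self.pre_trials < 0 or self.learn_trials < 0:
            raise InvalidSpecError("trial counts must be non-negative")

    @property
    def has_pre_phase(self) -> bool:
        return self.name != "direct" and self.pre_trials > 0

    def pre_terminal(self, env: EnvironmentSpec) -> Optional[int]:
        if self.name == "targeted":
            return env.goal
        if self.name == "mistargeted":
            if env.mistarget is None:
                raise InvalidSpecError(
                    f"mistargeted design needs a mistarget landmark; {env.name} has none"
                )
            return env.mistarget
        return None  # continuous: fixed-duration trials

    def validate(self, env: EnvironmentSpec) -> None:
        if self.name != "direct":
            self.pre_terminal(env)


@dataclass
class RunLog:
    """Per-trial records and parameter snapshots for one condition batch."""

    condition: str
    design: str
    agent_kind: str
    feature_kind: str
    env_name: str
    trials: pd.DataFrame
    snapshots: dict = field(default_factory=dict)  # (seed_index, trial) -> dict
    policies: dict = field(default_factory=dict)  # seed_index -> (n_trials, N) greedy actions
    policy_trials: list = field(default_factory=list)
    n_seeds: int = 0
    max_steps: int = 0

    def seed_trial_table(self) -> pd.DataFrame:
        return self.trials


def _condition_seed(master_seed: int, label: str, replicate: int) -> tuple[int, int]:
    """Independent (agent, protocol) seeds for one condition replicate.

    A counter-based scheme: the condition label is hashed so that the
    same design/agent/doors combination gets the same substreams no
    matter which batch it is run in.
    """
    crc = zlib.crc32(label.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, crc, replicate])
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


def make_agent(agent_kind: str, env, features, policy, seed: int, **kwargs):
    if agent_kind == "dsr":
        return DSRAgent(env, features, policy, seed=seed, **kwargs)
    if agent_kind == "dyna":
        kwargs.pop("zero_vector_goal", None)
        kwargs.pop("bootstrap", None)
        kwargs.pop("hidden", None)
        lr = kwargs.pop("lr_sf", None)
        if lr is not None:
            kwargs.setdefault("lr", lr)
        kwargs.pop("lr_reward", None)
        return DynaAgent(env, features, policy, seed=seed, **kwargs)
    raise InvalidSpecError(f"unknown agent kind {agent_kind!r}")


def _run_trial(
    agent,
    env: EnvironmentSpec,
    start_state: int,
    ctx: PhaseContext,
) -> tuple[int, bool, bool, float]:
    """Run one trial; returns (latency, goal_visited, ended_at_terminal, reward)."""
    s = start_state
    goal_visited = s == env.goal
    cum_reward = 0.0
    latency = ctx.max_steps
    ended_at_terminal = False
    for k in range(ctx.max_steps):
        a = agent.act(s)
        out = step(env, s, a, ctx, k)
        agent.observe(s, a, out.next_state, out.reward)
        cum_reward += out.reward
        s = out.next_state
        if s == env.goal:
            goal_visited = True
        if out.terminal:
            latency = k + 1
            ended_at_terminal = ctx.terminal_state is not None and s == ctx.terminal_state
            break
    return latency, goal_visited, ended_at_terminal, cum_reward


def run_design(
    env: EnvironmentSpec,
    features: FeatureMap,
    design: DesignSpec,
    policy: PolicySpec,
    *,
    agent_kind: str = "dsr",
    doors: tuple[bool, bool] = (False, False),
    n_seeds: int = 30,
    master_seed: int = 0,
    max_steps: Optional[int] = None,
    agent_kwargs: Optional[dict] = None,
    record_policies: bool = False,
    condition: Optional[str] = None,
) -> RunLog:
    """Execute one condition (design x agent x doors) for many seeds.

    ``doors`` gives the (pre-exposure, learning) door states. Snapshots
    of the agent parameters are stored at trials ``-pre_trials``, ``0``
    and ``learn_trials``.
    """
    design.validate(env)
    cap = env.max_steps if max_steps is None else int(max_steps)
    agent_kwargs = dict(agent_kwargs or {})
    label = condition or (
        f"{env.name}|{features.kind}|{design.name}|{agent_kind}"
        f"|doors{int(doors[0])}{int(doors[1])}"
    )
    rows: list[dict] = []
    snapshots: dict = {}
    policies: dict = {}
    policy_trials = list(range(-design.pre_trials, design.learn_trials))

    for rep in range(n_seeds):
        agent_seed, proto_seed = _condition_seed(master_seed, label, rep)
        proto_rng = np.random.default_rng(proto_seed)
        agent = make_agent(agent_kind, env, features, policy, agent_seed, **agent_kwargs)
        pol_rows = [] if record_policies else None
        snapshots[(rep, -design.pre_trials if design.has_pre_phase else 0)] = agent.snapshot()

        if design.has_pre_phase:
            terminal = design.pre_terminal(env)
            agent.set_phase(doors[0], terminal_state=terminal)
            ctx = PhaseContext(
                rewarded=False,
                terminal_state=terminal,
                doors_enabled=doors[0],
                max_steps=cap,
            )
            start_pool = np.array([*env.intermediates, env.start, env.goal])
            for t in range(design.pre_trials):
                if design.name == "continuous":
                    s0 = int(proto_rng.choice(start_pool))
                else:
                    s0 = env.start
                latency, visited, at_term, cum = _run_trial(agent, env, s0, ctx)
                if at_term:
                    agent.inject_terminal_self(terminal, design.pre_reward)
                rows.append(
                    dict(
                        seed=rep,
                        phase="pre",
                        trial=t - design.pre_trials,
                        latency=latency,
                        success=visited,
                        cum_reward=cum,
                    )
                )
                if pol_rows is not None:
                    pol_rows.append(agent.greedy_actions())
            snapshots[(rep, 0)] = agent.snapshot()

        agent.set_phase(doors[1], terminal_state=env.goal)
        ctx = PhaseContext(
            rewarded=True, terminal_state=env.goal, doors_enabled=doors[1], max_steps=cap
        )
        for t in range(design.learn_trials):
            latency, visited, at_term, cum = _run_trial(agent, env, env.start, ctx)
            if at_term:
                agent.inject_terminal_self(env.goal, design.learn_reward)
            rows.append(
                dict(
                    seed=rep,
                    phase="learn",
                    trial=t,
                    latency=latency,
                    success=visited,
                    cum_reward=cum,
                )
            )
            if pol_rows is not None:
                pol_rows.append(agent.greedy_actions())
        if design.learn_trials > 0 or not design.has_pre_phase:
            snapshots[(rep, design.learn_trials)] = agent.snapshot()
        if pol_rows is not None:
            policies[rep] = np.stack(pol_rows) if pol_rows else np.empty((0, env.n_states), int)

    trials = pd.DataFrame(rows)
    trials["condition"] = label
    return RunLog(
        condition=label,
        design=design.name,
        agent_kind=agent_kind,
        feature_kind=features.kind,
        env_name=env.name,
        trials=trials,
        snapshots=snapshots,
        policies=policies,
        policy_trials=policy_trials,
        n_seeds=n_seeds,
        max_steps=cap,
    )


# ---------------------------------------------------------------------------
# Door experiment (2x2 design plus doors-in-pre-exposure extensions)
# ---------------------------------------------------------------------------

DOOR_CONDITIONS: tuple[tuple[str, str, tuple[bool, bool]], ...] = (
    ("Direct-NoDoors", "direct", (False, False)),
    ("Direct-Doors", "direct", (False, True)),
    ("Targeted-NoDoors/NoDoors", "targeted", (False, False)),
    ("Targeted-NoDoors/Doors", "targeted", (False, True)),
    ("Targeted-Doors/NoDoors", "targeted", (True, False)),
    ("Targeted-Doors/Doors", "targeted", (True, True)),
)


def run_door_experiment(
    *,
    n_seeds: int = 30,
    pre_trials: int = 50,
    learn_trials: int = 50,
    master_seed: int = 0,
    agents: Sequence[str] = ("dsr", "dyna"),
    max_steps: int = 500,
    policy: Optional[PolicySpec] = None,
    agent_kwargs: Optional[dict] = None,
) -> dict[str, RunLog]:
    """Six door conditions x agent kinds in the one-hot Tolman maze.

    Condition labels use the "pre-exposure/learning" convention, e.g.
    ``Targeted-Doors/NoDoors`` means doors were active during
    pre-exposure but not during learning. A stricter 500-step cap makes
    the task time-constrained.
    """
    env = build_tolman_maze("onehot-72", max_steps=max_steps)
    features = onehot_features(env)
    policy = policy or PolicySpec(kind="softmax", beta=1.0)
    out: dict[str, RunLog] = {}
    for agent_kind in agents:
        for label, design_name, doors in DOOR_CONDITIONS:
            design = DesignSpec(
                design_name,
                pre_trials=0 if design_name == "direct" else pre_trials,
                learn_trials=learn_trials,
            )
            log = run_design(
                env,
                features,
                design,
                policy,
                agent_kind=agent_kind,
                doors=doors,
                n_seeds=n_seeds,
                master_seed=master_seed,
                max_steps=max_steps,
                agent_kwargs=agent_kwargs,
                condition=f"{agent_kind}:{label}",
            )
            out[f"{agent_kind}:{label}"] = log
    return out


# ---------------------------------------------------------------------------
# Generalization probe (novel-input test)
# ---------------------------------------------------------------------------


def run_generalization_probe(
    *,
    feature_kind: str = "image-like",
    n_seeds: int = 20,
    master_seed: int = 0,
    learn_trials: int = 50,
    width: int = 8,
    height: int = 6,
    held_out: Optional[tuple[int, int]] = None,
    D: int = 256,
    length_scale: float = 2.0,
    policy: Optional[PolicySpec] = None,
    agent_kwargs: Optional[dict] = None,
) -> tuple[np.ndarray, EnvironmentSpec, int]:
    """Train direct-learning agents, withholding one state from training.

    The held-out cell sits off the start-goal axis; every experience
    tuple that touches it is filtered from the replay buffer before
    training, so its successor features are never directly updated. The
    probe returns the extracted occupancy-matrix row of the held-out
    state (averaged over actions) for each seed, shape ``(n_seeds, N)``.
    """
    from .sr_agents import extract_deep_sr_matrix  # local import to avoid cycle

    env = build_gridworld(width, height)
    # default probe: an interior cell just off the start-goal diagonal,
    # adjacent to well-visited territory (a corner probe's neighborhood is
    # rarely visited and its occupancy row is dominated by noise)
    held = held_out or (width // 2, height // 2 - 1)
    held_id = int(np.flatnonzero((env.coords == np.array(held)).all(axis=1))[0])
    if held_id in (env.start, env.goal):
        raise ContractViolationError("held-out state must differ from start and goal")
    if feature_kind == "onehot":
        features = onehot_features(env)
    else:
        features = imagelike_features(env, D=D, length_scale=length_scale, seed=0)
    policy = policy or PolicySpec()
    design = DesignSpec("direct", pre_trials=0, learn_trials=learn_trials)
    kwargs = dict(agent_kwargs or {})
    kwargs["buffer_filter_state"] = held_id
    label = f"generalization|{env.name}|{feature_kind}"
    rows = np.empty((n_seeds, env.n_states))
    for rep in range(n_seeds):
        agent_seed, _ = _condition_seed(master_seed, label, rep)
        agent = make_agent("dsr", env, features, policy, agent_seed, **kwargs)
        agent.set_phase(False, terminal_state=env.goal)
        ctx = PhaseContext(
            rewarded=True, terminal_state=env.goal, doors_enabled=False, max_steps=env.max_steps
        )
        for _ in range(learn_trials):
            _, _, at_term, _ = _run_trial(agent, env, env.start, ctx)
            if at_term:
                agent.inject_terminal_self(env.goal, design.learn_reward)
        s, _, s2, _ = agent.buffer.tuples()
        if np.any(s == held_id) or np.any(s2 == held_id):
            raise ContractViolationError("held-out state leaked into the training buffer")
        c = np.mean(
            [extract_deep_sr_matrix(agent.model, features, a)[held_id] for a in range(4)],
            axis=0,
        )
        rows[rep] = c
    return rows, env, held_id
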