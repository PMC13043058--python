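"""Canonical study configurations.

Each function runs one of the packaged experiments end to end at either
the full scale (30 simulations, 50 pre-exposure + 50 learning trials,
matching the study conditions the environments and designs define) or a
reduced scale used where a full-scale run would be disproportionate to
the quantity being checked. The reduced problem sizes are fixed here,
in one place, and documented in the methods note.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import analysis as an
from .maze_env import build_gridworld, build_tolman_maze
from .protocols import (
    DesignSpec,
    RunLog,
    run_design,
    run_door_experiment,
    run_generalization_probe,
)
from .sr_agents import PolicySpec
from .state_features import onehot_features


def latent_design_study(
    master_seed: int = 0,
    n_seeds: int = 30,
    pre_trials: int = 50,
    learn_trials: int = 50,
    agent_kind: str = "dsr",
    designs: Sequence[str] = ("direct", "targeted", "continuous", "mistargeted"),
    policy: Optional[PolicySpec] = None,
    environment: str = "gridworld",
    feature_kind: str = "onehot",
    D: int = 2048,
) -> dict[str, RunLog]:
    """Task-design comparison in one environment (default: 10x10 one-hot
    gridworld with an epsilon-greedy policy).

    ``environment`` is ``gridworld``, ``tolman-onehot-72`` or
    ``tolman-image-30``; the mistargeted design only exists in arenas
    with a mistarget landmark.
    """
    if environment == "gridworld":
        env = build_gridworld(10, 10)
    else:
        env = build_tolman_maze(environment.removeprefix("tolman-"))
    if feature_kind == "onehot":
        features = onehot_features(env)
    else:
        from .state_features import imagelike_features

        features = imagelike_features(env, D=D)
    if isinstance(policy, dict):
        policy = PolicySpec(**policy)
    policy = policy or PolicySpec()
    logs = {}
    for name in designs:
        design = DesignSpec(
            name,
            pre_trials=0 if name == "direct" else pre_trials,
            learn_trials=learn_trials,
        )
        logs[name] = run_design(
            env,
            features,
            design,
            policy,
            agent_kind=agent_kind,
            n_seeds=n_seeds,
            master_seed=master_seed,
        )
    return logs


def tolman_optimality_study(
    master_seed: int = 0,
    n_seeds: int = 6,
    pre_trials: int = 15,
    learn_trials: int = 5,
) -> dict[str, RunLog]:
    """Targeted vs continuous pre-exposure in the 72-state Tolman maze,
    with per-trial greedy-policy tables recorded for the optimality trace.

    The reduced default scale (6 seeds, 15 pre-exposure trials) keeps the
    1500-step continuous trials tractable; the full study uses 30 and 50.
    """
    env = build_tolman_maze("onehot-72")
    features = onehot_features(env)
    policy = PolicySpec()
    logs = {}
    for name in ("targeted", "continuous"):
        design = DesignSpec(name, pre_trials=pre_trials, learn_trials=learn_trials)
        logs[name] = run_design(
            env,
            features,
            design,
            policy,
            n_seeds=n_seeds,
            master_seed=master_seed,
            record_policies=True,
        )
    return logs


def door_study(
    master_seed: int = 0,
    n_seeds: int = 10,
    pre_trials: int = 20,
    learn_trials: int = 50,
    agents: Sequence[str] = ("dsr", "dyna"),
) -> dict[str, RunLog]:
    """Six door conditions x agents, Tolman one-hot maze, 500-step cap,
    softmax policy (beta = 1).

    Learning runs the full 50 trials (the door effects unfold late under
    the strict cap); pre-exposure is shortened to 20 trials and seeds to
    10 to keep the batch tractable."""
    return run_door_experiment(
        n_seeds=n_seeds,
        pre_trials=pre_trials,
        learn_trials=learn_trials,
        master_seed=master_seed,
        agents=agents,
    )


def goal_update_ablation_study(
    master_seed: int = 0,
    n_seeds: int = 10,
    pre_trials: int = 50,
    learn_trials: int = 50,
) -> dict[str, RunLog]:
    """Default targeted agent vs one whose goal SF is regressed to the
    zero vector, in the gridworld."""
    env = build_gridworld(10, 10)
    features = onehot_features(env)
    policy = PolicySpec()
    design = DesignSpec("targeted", pre_trials=pre_trials, learn_trials=learn_trials)
    out = {}
    out["default"] = run_design(
        env, features, design, policy, n_seeds=n_seeds, master_seed=master_seed
    )
    out["zero-vector-goal"] = run_design(
        env,
        features,
        design,
        policy,
        n_seeds=n_seeds,
        master_seed=master_seed,
        agent_kwargs=dict(zero_vector_goal=True),
        condition="gridworld|onehot|targeted|dsr|zero-vector-goal",
    )
    return out


def generalization_study(
    master_seed: int = 0,
    n_seeds: int = 20,
    learn_trials: int = 50,
    D: int = 128,
) -> dict[str, np.ndarray]:
    """Novel-input probe in the 8x6 arena: per-seed goal-bias scores of
    the held-out state's occupancy row, for image-like vs one-hot codes.

    ``D`` is the image-like feature dimension; 128 keeps the linear SF
    maps small while staying well above the 48-state rank requirement.
    """
    scores = {}
    for kind in ("image-like", "onehot"):
        rows, env, held = run_generalization_probe(
            feature_kind=kind,
            n_seeds=n_seeds,
            master_seed=master_seed,
            learn_trials=learn_trials,
            D=D,
        )
        scores[kind] = np.array(
            [an.generalization_bias_score(row, env, held) for row in rows]
        )
    return scores
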