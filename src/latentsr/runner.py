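"""Configuration schema and reproducible batch execution.

An experiment is described by a YAML file with named sections (schema
validated; unknown keys rejected). Two shapes are accepted: a
``single`` run (environment + features + agent + design + policy +
doors + seeds) executed through :func:`latentsr.protocols.run_design`,
or a packaged ``study`` (design comparison, door experiment, optimality
trace, goal-update ablation, generalization probe) executed through
:mod:`latentsr.studies`. Outputs are written to
``<out>/<experiment>/<timestamp>/`` as ``config.yaml``,
``manifest.json``, ``trials.csv`` and ``snapshots.h5``.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import studies
from .maze_env import build_gridworld, build_tolman_maze
from .protocols import DesignSpec, RunLog, run_design
from .sr_agents import PolicySpec
from .state_features import imagelike_features, onehot_features

__version__ = "0.1.0"


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EnvironmentConfig(_Section):
    kind: Literal["gridworld", "tolman"] = "gridworld"
    width: int = 10
    height: int = 10
    variant: Literal["onehot-72", "image-30"] = "onehot-72"
    max_steps: Optional[int] = None
    reward_magnitude: float = 5.0


class FeatureConfig(_Section):
    kind: Literal["onehot", "image-like"] = "onehot"
    D: int = 2048
    length_scale: float = 2.0
    seed: int = 0


class AgentConfig(_Section):
    kind: Literal["dsr", "dyna"] = "dsr"
    gamma: float = 0.9
    lr_sf: float = 0.05
    lr_reward: float = 0.2
    batch_size: int = 32
    init: Literal["glorot", "zeros"] = "glorot"
    hidden: int = 0
    bootstrap: Literal["greedy", "policy"] = "greedy"
    goal_replay: bool = True
    n_goal_replays: int = 1
    zero_vector_goal: bool = False


class DesignConfig(_Section):
    name: Literal["direct", "targeted", "continuous", "mistargeted"] = "direct"
    pre_trials: int = 50
    learn_trials: int = 50
    learn_reward: float = 5.0


class PolicyConfig(_Section):
    kind: Literal["epsilon-greedy", "softmax"] = "epsilon-greedy"
    epsilon: float = 0.3
    beta: float = 1.0


class DoorsConfig(_Section):
    pre: bool = False
    learn: bool = False


class SeedsConfig(_Section):
    n_seeds: int = 30
    master_seed: int = 0


class OutputConfig(_Section):
    record_policies: bool = False


class StudyConfig(_Section):
    name: Literal["designs", "doors", "optimality", "ablation", "generalization"]
    params: dict = {}


class ExperimentConfig(_Section):
    """Top-level experiment description; exactly one of ``study`` or the
    single-run sections drives execution."""

    experiment: str = "experiment"
    study: Optional[StudyConfig] = None
    environment: EnvironmentConfig = EnvironmentConfig()
    features: FeatureConfig = FeatureConfig()
    agent: AgentConfig = AgentConfig()
    design: DesignConfig = DesignConfig()
    policy: PolicyConfig = PolicyConfig()
    doors: DoorsConfig = DoorsConfig()
    seeds: SeedsConfig = SeedsConfig()
    output: OutputConfig = OutputConfig()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.model_validate(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


class ConfigSchemaError(ValueError):
    """Invalid experiment configuration, with the offending field path."""


def load_config(path) -> ExperimentConfig:
    try:
        return ExperimentConfig.from_yaml(path)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigSchemaError(f"invalid config {path}: {locs}") from exc


def _build_env(cfg: EnvironmentConfig):
    if cfg.kind == "gridworld":
        return build_gridworld(
            cfg.width,
            cfg.height,
            max_steps=cfg.max_steps or 300,
            reward_magnitude=cfg.reward_magnitude,
        )
    return build_tolman_maze(
        cfg.variant, max_steps=cfg.max_steps, reward_magnitude=cfg.reward_magnitude
    )


def _build_features(env, cfg: FeatureConfig):
    if cfg.kind == "onehot":
        return onehot_features(env)
    return imagelike_features(env, D=cfg.D, length_scale=cfg.length_scale, seed=cfg.seed)


SMOKE_SEEDS = 5
SMOKE_TRIALS = 15


def run_experiment(
    config,
    scale: str = "full",
    out: str | Path = "runs",
    master_seed: Optional[int] = None,
) -> Path:
    """Execute a configured experiment and write its outputs.

    ``scale="smoke"`` shrinks the number of seeds to 5 and trial counts
    to 15 without touching any other parameter. Returns the run
    directory.
    """
    if not isinstance(config, ExperimentConfig):
        config = load_config(config)
    if scale not in ("full", "smoke"):
        raise ConfigSchemaError(f"unknown scale {scale!r}")
    cfg = config.model_copy(deep=True)
    if master_seed is not None:
        cfg.seeds.master_seed = int(master_seed)
    if scale == "smoke":
        cfg.seeds.n_seeds = min(cfg.seeds.n_seeds, SMOKE_SEEDS)
        cfg.design.pre_trials = min(cfg.design.pre_trials, SMOKE_TRIALS)
        cfg.design.learn_trials = min(cfg.design.learn_trials, SMOKE_TRIALS)

    stamp = _dt.datetime.now().strftime("%Y%m%dT%H%M%S")
    run_dir = Path(out) / cfg.experiment / stamp
    run_dir.mkdir(parents=True, exist_ok=True)

    logs = _execute(cfg, scale)

    trials = pd.concat([log.trials for log in logs.values()], ignore_index=True)
    trials.to_csv(run_dir / "trials.csv", index=False)
    with h5py.File(run_dir / "snapshots.h5", "w") as f:
        for name, log in logs.items():
            grp = f.create_group(name)
            for (rep, trial), snap in log.snapshots.items():
                for key, arr in snap.items():
                    grp.create_dataset(f"seed{rep}/trial{trial}/{key}", data=arr)
    config_text = cfg.to_yaml()
    (run_dir / "config.yaml").write_text(config_text)
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "scale": scale,
        "master_seed": cfg.seeds.master_seed,
        "n_seeds": cfg.seeds.n_seeds,
        "conditions": list(logs),
        "schema_version": 1,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


def _execute(cfg: ExperimentConfig, scale: str) -> dict[str, RunLog]:
    if cfg.study is not None:
        return _execute_study(cfg, scale)
    env = _build_env(cfg.environment)
    features = _build_features(env, cfg.features)
    policy = PolicySpec(
        kind=cfg.policy.kind, epsilon=cfg.policy.epsilon, beta=cfg.policy.beta
    )
    design = DesignSpec(
        cfg.design.name,
        pre_trials=0 if cfg.design.name == "direct" else cfg.design.pre_trials,
        learn_trials=cfg.design.learn_trials,
        learn_reward=cfg.design.learn_reward,
    )
    agent_cfg = cfg.agent.model_dump()
    agent_kind = agent_cfg.pop("kind")
    if agent_kind == "dyna":
        agent_cfg = {
            "gamma": agent_cfg["gamma"],
            "lr": agent_cfg["lr_sf"],
            "batch_size": agent_cfg["batch_size"],
            "init": agent_cfg["init"],
            "goal_replay": agent_cfg["goal_replay"],
            "n_goal_replays": agent_cfg["n_goal_replays"],
        }
    log = run_design(
        env,
        features,
        design,
        policy,
        agent_kind=agent_kind,
        doors=(cfg.doors.pre, cfg.doors.learn),
        n_seeds=cfg.seeds.n_seeds,
        master_seed=cfg.seeds.master_seed,
        agent_kwargs=agent_cfg,
        record_policies=cfg.output.record_policies,
    )
    return {log.condition: log}


def _execute_study(cfg: ExperimentConfig, scale: str) -> dict[str, RunLog]:
    params = dict(cfg.study.params)
    params.setdefault("master_seed", cfg.seeds.master_seed)
    if scale == "smoke":
        params["n_seeds"] = min(params.get("n_seeds", cfg.seeds.n_seeds), SMOKE_SEEDS)
        for key in ("pre_trials", "learn_trials"):
            if key in params:
                params[key] = min(params[key], SMOKE_TRIALS)
    else:
        params.setdefault("n_seeds", cfg.seeds.n_seeds)
    name = cfg.study.name
    if name == "designs":
        return studies.latent_design_study(**params)
    if name == "doors":
        return studies.door_study(**params)
    if name == "optimality":
        return studies.tolman_optimality_study(**params)
    if name == "ablation":
        return studies.goal_update_ablation_study(**params)
    if name == "generalization":
        scores = studies.generalization_study(**params)
        # wrap scores in a minimal trial table so outputs share one schema
        rows = []
        for kind, vals in scores.items():
            for i, v in enumerate(vals):
                rows.append(
                    dict(
                        seed=i,
                        phase="probe",
                        trial=0,
                        latency=np.nan,
                        success=np.nan,
                        cum_reward=np.nan,
                        bias_score=v,
                        condition=f"generalization|{kind}",
                    )
                )
        log = RunLog(
            condition="generalization",
            design="direct",
            agent_kind="dsr",
            feature_kind="both",
            env_name="gridworld-8x6",
            trials=pd.DataFrame(rows),
        )
        return {"generalization": log}
    raise ConfigSchemaError(f"unknown study {name!r}")


def list_experiments() -> dict[str, Path]:
    """Packaged experiment catalog: name -> config path."""
    root = resources.files("latentsr.configs")
    out = {}
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            out[entry.name[: -len(".yaml")]] = entry
    return out
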