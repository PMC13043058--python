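"""Analyses of run logs: learning curves, SF-structure similarity,
value maps from a ground-truth reward, policy optimality and
between-condition ordering statistics.

All functions here are pure functions of :class:`~latentsr.protocols.RunLog`
contents (plus the environment geometry); they never touch agents or
environments' mutable state.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .maze_env import EnvironmentSpec, N_ACTIONS
from .protocols import RunLog
from .state_features import FeatureMap


class SchemaError(ValueError):
    """Raised when a run log is missing required records."""


# ---------------------------------------------------------------------------
# Behavioral summaries
# ---------------------------------------------------------------------------


def behavioral_summary(log: RunLog) -> pd.DataFrame:
    """Per-trial mean escape latency, its standard error over seeds, and
    the fraction of seeds that reached the goal (success rate)."""
    df = log.trials
    if df.empty:
        raise SchemaError("run log contains no trials")
    counts = df.groupby("trial")["latency"].count()
    if counts.nunique() != 1:
        raise SchemaError("trials are missing for some seeds")
    out = (
        df.groupby(["phase", "trial"])
        .agg(
            mean_latency=("latency", "mean"),
            sem_latency=("latency", lambda x: stats.sem(x) if len(x) > 1 else 0.0),
            success_rate=("success", "mean"),
            n=("latency", "count"),
        )
        .reset_index()
        .sort_values("trial")
        .reset_index(drop=True)
    )
    out["condition"] = log.condition
    return out


def per_seed_window_means(
    log: RunLog, window: tuple[int, int] = (0, 4), phase: str = "learn"
) -> np.ndarray:
    """Mean latency per seed over an inclusive trial window."""
    df = log.trials
    sel = df[(df["phase"] == phase) & df["trial"].between(window[0], window[1])]
    if sel.empty:
        raise SchemaError(f"no trials in window {window} for phase {phase!r}")
    return sel.groupby("seed")["latency"].mean().sort_index().to_numpy()


def condition_ordering_test(
    logs: dict[str, RunLog],
    window: tuple[int, int] = (0, 4),
    alpha: float = 0.05,
) -> dict:
    """Pairwise rank-based comparison of early-learning latencies.

    For every pair of conditions, per-seed mean latencies over the
    window are compared with a Mann-Whitney U test. The report gives the
    direction of the means and one- and two-sided p values; no
    multiplicity correction is applied (pairs are reported individually).
    """
    names = list(logs)
    if len(names) < 2:
        raise SchemaError("ordering test needs at least two conditions")
    means = {name: per_seed_window_means(logs[name], window) for name in names}
    report: dict = {"window": window, "alpha": alpha, "pairs": {}}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa, xb = means[a], means[b]
            mw2 = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            mwl = stats.mannwhitneyu(xa, xb, alternative="less")
            report["pairs"][f"{a} vs {b}"] = {
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "faster": a if xa.mean() < xb.mean() else b,
                "p_two_sided": float(mw2.pvalue),
                "p_a_less": float(mwl.pvalue),
                "significant": bool(mw2.pvalue < alpha),
            }
    return report


# ---------------------------------------------------------------------------
# SF-structure similarity
# ---------------------------------------------------------------------------


def _state_sf_vectors(snapshot: dict, mode: str, w: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-state SF vectors from a snapshot, shape (N, A*D) or (N, D)."""
    sf = snapshot["sf"]  # (A, N, D)
    if mode == "concat":
        return np.concatenate([sf[a] for a in range(sf.shape[0])], axis=1)
    if mode == "greedy":
        q = np.stack([sf[a] @ w for a in range(sf.shape[0])], axis=1)  # (N, A)
        best = np.argmax(q, axis=1)
        return sf[best, np.arange(sf.shape[1])]
    raise SchemaError(f"unknown similarity mode {mode!r}")


def sf_similarity_profile(
    probe_log: RunLog,
    reference_log: RunLog,
    env: EnvironmentSpec,
    probe_trial: int = 0,
    reference_trial: Optional[int] = None,
    mode: str = "concat",
) -> pd.DataFrame:
    """Cosine similarity between a probe agent's SF (end of pre-exposure)
    and a reference agent's SF (end of learning), state by state.

    Seeds are paired (probe seed i against reference seed i) and the
    per-state similarity is averaged over pairs. States are ordered by
    shortest-path distance to the goal. Columns: ``state``, ``dist_to_goal``,
    ``similarity`` plus the per-pair matrix in ``attrs['per_pair']``.
    """
    if reference_trial is None:
        reference_trial = max(t for (_, t) in reference_log.snapshots)
    reps = sorted(
        {r for (r, t) in probe_log.snapshots if t == probe_trial}
        & {r for (r, t) in reference_log.snapshots if t == reference_trial}
    )
    if not reps:
        raise SchemaError("no common seeds with the requested snapshot trials")
    sims = []
    for rep in reps:
        ps = probe_log.snapshots[(rep, probe_trial)]
        rs = reference_log.snapshots[(rep, reference_trial)]
        pv = _state_sf_vectors(ps, mode, ps.get("w"))
        rv = _state_sf_vectors(rs, mode, rs.get("w"))
        if pv.shape != rv.shape:
            raise SchemaError("probe and reference snapshots have mismatched dimensions")
        num = (pv * rv).sum(axis=1)
        den = np.linalg.norm(pv, axis=1) * np.linalg.norm(rv, axis=1)
        sims.append(np.where(den > 0, num / np.maximum(den, 1e-300), 0.0))
    per_pair = np.stack(sims)  # (n_pairs, N)
    dist = env.distances_to(env.goal)
    df = pd.DataFrame(
        {
            "state": np.arange(env.n_states),
            "dist_to_goal": dist,
            "similarity": per_pair.mean(axis=0),
        }
    ).sort_values("dist_to_goal", kind="stable").reset_index(drop=True)
    df.attrs["per_pair"] = per_pair
    return df


def goal_quartile_states(env: EnvironmentSpec) -> np.ndarray:
    """The quartile of states with the smallest path distance to the goal."""
    dist = env.distances_to(env.goal)
    order = np.argsort(dist, kind="stable")
    k = max(1, env.n_states // 4)
    return order[:k]


# ---------------------------------------------------------------------------
# Value maps and policy optimality
# ---------------------------------------------------------------------------


def q_map_from_ground_truth(
    snapshot: dict, env: EnvironmentSpec, features: FeatureMap
) -> tuple[np.ndarray, np.ndarray]:
    """Q values from a SF snapshot and an idealized reward of 1 at the goal.

    The reward weights ``w*`` solve ``Phi w = e_goal`` in the
    least-squares sense (for one-hot features, ``w* = e_goal``), so
    ``Q(s, a) = m(s, a) . w*`` isolates what the successor structure
    alone says about the goal. Returns ``(raw, normalized)`` arrays of
    shape (N, A); the normalized copy is min-max scaled to [0, 1].
    """
    e_goal = np.zeros(env.n_states)
    e_goal[env.goal] = 1.0
    gram = features.gram()
    w_star = features.matrix.T @ np.linalg.solve(gram, e_goal)
    sf = snapshot["sf"]  # (A, N, D)
    raw = np.stack([sf[a] @ w_star for a in range(sf.shape[0])], axis=1)
    lo, hi = raw.min(), raw.max()
    norm = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    return raw, norm


def optimality_trace(
    log: RunLog,
    env: EnvironmentSpec,
    doors_enabled: bool = False,
    phase: Optional[str] = "pre",
) -> pd.DataFrame:
    """Fraction of evaluated states where the recorded greedy action lies
    on a shortest path to the goal, per seed and trial.

    Dead-end states (one viable action) and the goal itself are excluded
    from the evaluated set. Requires the run to have recorded policies.
    """
    if not log.policies:
        raise SchemaError("run log has no recorded policy tables")
    optimal = env.optimal_actions(doors_enabled)
    dead = set(env.dead_end_states(doors_enabled).tolist())
    evaluated = [
        s for s in range(env.n_states) if s not in dead and s != env.goal and optimal[s]
    ]
    trial_ids = np.asarray(log.policy_trials)
    if phase == "pre":
        keep = trial_ids < 0
    elif phase == "learn":
        keep = trial_ids >= 0
    else:
        keep = np.ones_like(trial_ids, dtype=bool)
    rows = []
    for rep, table in log.policies.items():
        for j in np.flatnonzero(keep):
            actions = table[j]
            ratio = float(np.mean([actions[s] in optimal[s] for s in evaluated]))
            rows.append(dict(seed=rep, trial=int(trial_ids[j]), ratio=ratio))
    return pd.DataFrame(rows)


def optimality_ratio_from_actions(
    actions: np.ndarray, env: EnvironmentSpec, doors_enabled: bool = False
) -> float:
    """Optimality ratio for one explicit greedy-action table."""
    optimal = env.optimal_actions(doors_enabled)
    dead = set(env.dead_end_states(doors_enabled).tolist())
    evaluated = [
        s for s in range(env.n_states) if s not in dead and s != env.goal and optimal[s]
    ]
    return float(np.mean([actions[s] in optimal[s] for s in evaluated]))


# ---------------------------------------------------------------------------
# Generalization bias
# ---------------------------------------------------------------------------


def generalization_bias_score(
    sr_row: np.ndarray,
    env: EnvironmentSpec,
    held_out_state: int,
    k: int = 10,
) -> float:
    """Quantifies goal-directedness of a novel state's occupancy row.

    An invented summary of the qualitative "trajectory toward the goal"
    pattern: take the row's top-``k`` states by value (ties at the
    threshold included), weight them by their positive mass, and compute
    the weighted mean decrease in distance-to-goal relative to the
    held-out state; subtract the same quantity under a uniform row.
    Positive scores mean the represented mass sits goal-ward of the
    novel state; a uniform row scores exactly zero.
    """
    row = np.asarray(sr_row, dtype=float)
    dist = env.distances_to(env.goal)
    drop = dist[held_out_state] - dist  # positive for states closer to the goal
    uniform = float(drop.mean())
    if row.size <= k:
        selected = np.arange(row.size)
    else:
        thresh = np.sort(row)[-k]
        selected = np.flatnonzero(row >= thresh)
    weights = np.clip(row[selected], 0.0, None)
    total = weights.sum()
    if total == 0.0:
        return 0.0
    weighted = float((weights / total) @ drop[selected])
    return weighted - uniform


# ---------------------------------------------------------------------------
# Plots (thin matplotlib helpers used by the CLI)
# ---------------------------------------------------------------------------


def plot_learning_curves(summaries: dict[str, pd.DataFrame], ax=None):
    """Escape-latency curves (mean +/- SEM band) for several conditions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, summary in summaries.items():
        s = summary.sort_values("trial")
        ax.plot(s["trial"], s["mean_latency"], label=name)
        ax.fill_between(
            s["trial"],
            s["mean_latency"] - s["sem_latency"],
            s["mean_latency"] + s["sem_latency"],
            alpha=0.25,
        )
    ax.axvline(0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("trial (pre-exposure < 0, learning >= 0)")
    ax.set_ylabel("escape latency (steps)")
    ax.legend(fontsize=8)
    return ax
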