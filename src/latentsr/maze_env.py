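"""Discrete maze environments for latent-learning simulations.

The environments are small deterministic grid graphs: an open arena
("gridworld") and Tolman-style T-mazes with dead-end alleys and optional
one-way doors. States are grid cells, actions are the four compass moves,
and an action mask removes wall-violating moves so the agent can never
stand still. Doors, when enabled, additionally remove the reverse
direction of designated passage edges, forcing forward progress along the
goal-ward corridor.

Coordinates are 0-based ``(col, row)`` with the origin at the top-left:
``up`` is ``(0, -1)``, ``right`` is ``(+1, 0)``, ``down`` is ``(0, +1)``
and ``left`` is ``(-1, 0)``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

ACTIONS: tuple[str, ...] = ("up", "right", "down", "left")
ACTION_DELTAS: tuple[tuple[int, int], ...] = ((0, -1), (1, 0), (0, 1), (-1, 0))
N_ACTIONS = 4

#: characters understood by the plain-text maze format
WALL_CHAR = "#"
DOOR_CHARS = {"^": 0, ">": 1, "v": 2, "<": 3}


class InvalidSpecError(ValueError):
    """Raised when an environment description violates its invariants."""


class ContractViolationError(RuntimeError):
    """Raised when an operation is called outside its contract."""


def reverse_action(action: int) -> int:
    """Opposite compass move (up<->down, left<->right)."""
    return (action + 2) % 4


@dataclass(frozen=True)
class StepOutcome:
    """Result of one environment transition."""

    next_state: int
    reward: float
    terminal: bool
    step_index: int


@dataclass(frozen=True)
class PhaseContext:
    """Active task-phase rules applied by :func:`step`.

    Parameters
    ----------
    rewarded
        Whether arrival at the goal pays the environment's reward
        magnitude (learning phase) or nothing (pre-exposure).
    terminal_state
        State whose arrival ends the trial, or ``None`` for fixed-duration
        (continuous) trials that only end at the step limit.
    doors_enabled
        Whether one-way doors are active during this phase.
    max_steps
        Per-trial step limit for this phase.
    """

    rewarded: bool
    terminal_state: Optional[int]
    doors_enabled: bool
    max_steps: int


class EnvironmentSpec:
    """Deterministic maze graph with landmarks and optional one-way doors.

    States are integers ``0..N-1`` in row-major order of the occupied grid
    cells. The base transition table (doors disabled) is symmetric; the
    door table removes exactly the reverse edge of each door edge.
    """

    def __init__(
        self,
        name: str,
        coords: np.ndarray,
        transitions: dict[tuple[int, int], int],
        doors: Iterable[tuple[int, int]] = (),
        *,
        start: int,
        goal: int,
        intermediates: Sequence[int] = (),
        mistarget: Optional[int] = None,
        max_steps: int = 300,
        reward_magnitude: float = 5.0,
    ) -> None:
        self.name = name
        self.coords = np.asarray(coords, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise InvalidSpecError("coords must be an (N, 2) array of (col, row)")
        n = self.coords.shape[0]
        self.start = int(start)
        self.goal = int(goal)
        self.intermediates = tuple(int(i) for i in intermediates)
        self.mistarget = None if mistarget is None else int(mistarget)
        self.max_steps = int(max_steps)
        self.reward_magnitude = float(reward_magnitude)
        self.doors = frozenset((int(u), int(v)) for u, v in doors)

        table = np.full((n, N_ACTIONS), -1, dtype=int)
        for (s, a), s2 in transitions.items():
            table[s, a] = s2
        self._table_open = table
        self._table_doors = table.copy()
        for u, v in self.doors:
            # remove the reverse edge v -> u
            hits = np.flatnonzero(self._table_doors[v] == u)
            if hits.size == 0:
                raise InvalidSpecError(f"door edge ({u},{v}) has no reverse edge to remove")
            self._table_doors[v, hits] = -1
        self._allowed_open = [np.flatnonzero(row >= 0) for row in self._table_open]
        self._allowed_doors = [np.flatnonzero(row >= 0) for row in self._table_doors]
        self._validate()

    # -- basic queries ---------------------------------------------------

    @property
    def n_states(self) -> int:
        return self.coords.shape[0]

    def transition_table(self, doors_enabled: bool = False) -> np.ndarray:
        """(N, 4) next-state table; -1 marks a masked action."""
        return self._table_doors if doors_enabled else self._table_open

    def allowed_actions(self, state: int, doors_enabled: bool = False) -> np.ndarray:
        allowed = self._allowed_doors if doors_enabled else self._allowed_open
        return allowed[state]

    def next_state(self, state: int, action: int, doors_enabled: bool = False) -> int:
        s2 = self.transition_table(doors_enabled)[state, action]
        if s2 < 0:
            raise ContractViolationError(
                f"action {ACTIONS[action]} is masked in state {state}"
            )
        return int(s2)

    def dead_end_states(self, doors_enabled: bool = False) -> np.ndarray:
        """States with exactly one allowed action (alley termini)."""
        allowed = self._allowed_doors if doors_enabled else self._allowed_open
        return np.array([s for s in range(self.n_states) if allowed[s].size == 1], dtype=int)

    # -- graph measures --------------------------------------------------

    def distances_to(self, target: int, doors_enabled: bool = False) -> np.ndarray:
        """Shortest number of allowed moves from every state to ``target``.

        Runs a breadth-first search over reversed edges, so one-way doors
        are respected. Unreachable states get ``np.inf``.
        """
        table = self.transition_table(doors_enabled)
        preds: list[list[int]] = [[] for _ in range(self.n_states)]
        for s in range(self.n_states):
            for a in range(N_ACTIONS):
                s2 = table[s, a]
                if s2 >= 0:
                    preds[s2].append(s)
        dist = np.full(self.n_states, np.inf)
        dist[target] = 0.0
        queue = deque([target])
        while queue:
            v = queue.popleft()
            for u in preds[v]:
                if not np.isfinite(dist[u]):
                    dist[u] = dist[v] + 1
                    queue.append(u)
        return dist

    def pairwise_distances(self) -> np.ndarray:
        """All-pairs shortest-path distances with doors disabled."""
        return np.stack([self.distances_to(t) for t in range(self.n_states)], axis=1)

    def optimal_actions(self, doors_enabled: bool = False) -> list[set[int]]:
        """Per state, the allowed actions lying on a shortest path to the goal."""
        dist = self.distances_to(self.goal, doors_enabled)
        table = self.transition_table(doors_enabled)
        out: list[set[int]] = []
        for s in range(self.n_states):
            best: set[int] = set()
            for a in self.allowed_actions(s, doors_enabled):
                s2 = table[s, a]
                if np.isfinite(dist[s2]) and dist[s2] == dist[s] - 1:
                    best.add(int(a))
            out.append(best)
        return out

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        n = self.n_states
        table = self._table_open
        if n < 2:
            raise InvalidSpecError("environment needs at least two states")
        if np.any(table >= n):
            raise InvalidSpecError("transition leaves the state set")
        for s in range(n):
            if self._allowed_open[s].size == 0 or self._allowed_doors[s].size == 0:
                raise InvalidSpecError(f"state {s} has no allowed action")
        # doors-off symmetry
        for s in range(n):
            for a in range(N_ACTIONS):
                s2 = table[s, a]
                if s2 >= 0 and table[s2, reverse_action(a)] != s:
                    raise InvalidSpecError(
                        f"base move {s}->{s2} has no symmetric reverse"
                    )
        landmarks = [self.start, self.goal, *self.intermediates]
        if self.mistarget is not None:
            landmarks.append(self.mistarget)
        for lm in landmarks:
            if not 0 <= lm < n:
                raise InvalidSpecError(f"landmark {lm} outside state set")
        if len(set(landmarks)) != len(landmarks):
            raise InvalidSpecError("landmark states must be distinct")
        if not np.all(np.isfinite(self.distances_to(self.start))):
            raise InvalidSpecError("maze is not connected (doors disabled)")


# -- module-level operation surface ------------------------------------------


def allowed_actions(env: EnvironmentSpec, state: int, doors_enabled: bool = False) -> np.ndarray:
    """Ordered subset of actions allowed in ``state`` under the mask."""
    return env.allowed_actions(state, doors_enabled)


def step(
    env: EnvironmentSpec,
    state: int,
    action: int,
    ctx: PhaseContext,
    step_index: int = 0,
) -> StepOutcome:
    """Apply one action under the active phase rules.

    Reward is paid only on arrival at the goal while the phase is
    rewarded; the trial terminates on arrival at the phase's terminal
    state or when the step limit is reached.
    """
    s2 = env.next_state(state, action, ctx.doors_enabled)
    reward = env.reward_magnitude if (ctx.rewarded and s2 == env.goal) else 0.0
    terminal = (ctx.terminal_state is not None and s2 == ctx.terminal_state) or (
        step_index + 1 >= ctx.max_steps
    )
    return StepOutcome(next_state=s2, reward=reward, terminal=terminal, step_index=step_index)


# -- builders ----------------------------------------------------------------


def _grid_transitions(occupied: dict[tuple[int, int], int]) -> dict[tuple[int, int], int]:
    trans: dict[tuple[int, int], int] = {}
    for (x, y), s in occupied.items():
        for a, (dx, dy) in enumerate(ACTION_DELTAS):
            s2 = occupied.get((x + dx, y + dy))
            if s2 is not None:
                trans[(s, a)] = s2
    return trans


def _default_gridworld_landmarks(width: int, height: int) -> dict:
    """Landmark cells for an open arena: start bottom-left, goal top-right,
    mistarget in the opposite far corner region, intermediate starts spread
    over the arena. All positions are configurable by the caller."""

    def cell(x: int, y: int) -> tuple[int, int]:
        return (min(max(x, 0), width - 1), min(max(y, 0), height - 1))

    s = cell(1, height - 2)
    g = cell(width - 2, 1)
    if s == g:  # tiny arenas: fall back to opposite corners
        s = (0, height - 1)
        g = (width - 1, 0)
    taken = {s, g}
    m = cell(width - 2, height - 2)
    if m in taken:
        m = None
    else:
        taken.add(m)
    candidates = [
        cell(1, 1),
        cell(width // 2, height // 2),
        cell(1, height // 2),
        cell(width - 2, height // 2),
        cell(width // 2, 1),
        cell(width // 2, height - 2),
    ]
    inter = []
    for c in candidates:
        if c not in taken:
            inter.append(c)
            taken.add(c)
    return {"start": s, "goal": g, "mistarget": m, "intermediates": inter[:4]}


def build_gridworld(
    width: int,
    height: int,
    *,
    landmarks: Optional[dict] = None,
    max_steps: int = 300,
    reward_magnitude: float = 5.0,
) -> EnvironmentSpec:
    """Open rectangular arena with four-neighbour moves and no doors.

    ``landmarks`` may override any of ``start``, ``goal``, ``mistarget``
    and ``intermediates`` as ``(col, row)`` cells.
    """
    if width < 2 or height < 2:
        raise InvalidSpecError("gridworld needs width, height >= 2")
    occupied = {(x, y): y * width + x for y in range(height) for x in range(width)}
    coords = np.array([(x, y) for y in range(height) for x in range(width)])
    marks = _default_gridworld_landmarks(width, height)
    if landmarks:
        marks.update(landmarks)

    def sid(c):
        return None if c is None else occupied[tuple(c)]

    return EnvironmentSpec(
        name=f"gridworld-{width}x{height}",
        coords=coords,
        transitions=_grid_transitions(occupied),
        start=sid(marks["start"]),
        goal=sid(marks["goal"]),
        mistarget=sid(marks.get("mistarget")),
        intermediates=[sid(c) for c in marks.get("intermediates", ())],
        max_steps=max_steps,
        reward_magnitude=reward_magnitude,
    )


def load_maze_text(
    text: str,
    *,
    name: str = "maze",
    max_steps: int = 1000,
    reward_magnitude: float = 5.0,
) -> EnvironmentSpec:
    """Parse a plain-text maze description.

    One character per cell: ``#`` wall, ``.`` corridor, ``S`` start,
    ``G`` goal, ``M`` mistarget, ``I`` intermediate start, and
    ``^ v < >`` a corridor cell whose passage is one-way along the arrow
    when doors are enabled.
    """
    rows = [line.rstrip("\n") for line in text.splitlines() if line.strip()]
    occupied: dict[tuple[int, int], int] = {}
    chars: dict[tuple[int, int], str] = {}
    sid = 0
    for y, row in enumerate(rows):
        for x, ch in enumerate(row):
            if ch in (WALL_CHAR, " "):
                continue
            occupied[(x, y)] = sid
            chars[(x, y)] = ch
            sid += 1
    if not occupied:
        raise InvalidSpecError("maze file contains no corridor cells")
    coords = np.array(sorted(occupied, key=lambda c: occupied[c]))
    start = goal = mistarget = None
    intermediates: list[int] = []
    doors: set[tuple[int, int]] = set()
    for (x, y), ch in chars.items():
        s = occupied[(x, y)]
        if ch == "S":
            start = s
        elif ch == "G":
            goal = s
        elif ch == "M":
            mistarget = s
        elif ch == "I":
            intermediates.append(s)
        elif ch in DOOR_CHARS:
            a = DOOR_CHARS[ch]
            dx, dy = ACTION_DELTAS[a]
            before = occupied.get((x - dx, y - dy))
            after = occupied.get((x + dx, y + dy))
            if before is not None:
                doors.add((before, s))
            if after is not None:
                doors.add((s, after))
        elif ch != ".":
            raise InvalidSpecError(f"unknown maze character {ch!r} at {(x, y)}")
    if start is None or goal is None:
        raise InvalidSpecError("maze must mark S and G cells")
    return EnvironmentSpec(
        name=name,
        coords=coords,
        transitions=_grid_transitions(occupied),
        doors=doors,
        start=start,
        goal=goal,
        intermediates=intermediates,
        mistarget=mistarget,
        max_steps=max_steps,
        reward_magnitude=reward_magnitude,
    )


#: per-variant packaged layout and default step limit
_TOLMAN_VARIANTS = {
    "onehot-72": ("tolman72.txt", 1500),
    "image-30": ("tolman30.txt", 150),
}


def build_tolman_maze(
    variant: str,
    *,
    max_steps: Optional[int] = None,
    reward_magnitude: float = 5.0,
) -> EnvironmentSpec:
    """Tolman-style multiple-unit T-maze from a packaged layout file.

    ``onehot-72`` is the 72-state maze (14 choice units, three-cell blind
    alleys) used with one-hot codes; ``image-30`` is the coarse 30-state
    maze (one-cell alleys) used with image-like features.
    """
    if variant not in _TOLMAN_VARIANTS:
        raise InvalidSpecError(
            f"unknown Tolman variant {variant!r}; options: {sorted(_TOLMAN_VARIANTS)}"
        )
    fname, default_cap = _TOLMAN_VARIANTS[variant]
    text = resources.files("latentsr.mazes").joinpath(fname).read_text()
    return load_maze_text(
        text,
        name=f"tolman-{variant}",
        max_steps=default_cap if max_steps is None else max_steps,
        reward_magnitude=reward_magnitude,
    )
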