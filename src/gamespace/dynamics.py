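"""The self-interested dynamic: institutional preferences and hill climbing.

Agents evaluate whole games — not outcomes — by three boolean features
relative to a *focal* player:

* **stable**: the game has exactly one Nash equilibrium in total.  For
  two players the count includes the mixed equilibrium, which exists
  exactly when the pure count differs from one: zero pure equilibria
  leave a unique mixed one (stable, not predictable), while two pure
  equilibria come with a third, mixed one (unstable).
* **predictable**: exactly one *pure-strategy* equilibrium.
* **efficient**: some counted equilibrium outcome pays the focal player
  the top rank ``2**n`` (the mixed equilibrium has no outcome and never
  counts as efficient).

Preferences between games are lexicographic in the order stable >
predictable > efficient.  A trajectory repeatedly moves to a uniformly
chosen most-preferred strictly better neighbour; where no neighbour is
strictly preferred, preferences are neutral and the trajectory drifts
across the equal-feature plateau toward the nearest game that does have
a strict improvement.  It terminates when the plateau offers none —
which in the two-player space happens exactly at the *attractors*:
games with a unique pure equilibrium paying the focal player the
maximum, forming one contiguous neutral basin.

For n > 2 players mixed equilibria are not computed; stability and
predictability collapse to "exactly one pure equilibrium", which is all
the attractor definition needs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .equilibria import PlayResult, UnsupportedGameError, play_game, pure_nash_mask
from .games import InvariantError, OrdinalGame, canonicalize, neighbors

__all__ = [
    "FeatureVector",
    "TrajectoryRecord",
    "AttractorReport",
    "game_features",
    "is_attractor",
    "prefer",
    "choose_next",
    "run_trajectory",
    "attractor_set",
    "attractor_counts",
    "neighbor_graph",
    "graph_distance",
]


@dataclass(frozen=True)
class FeatureVector:
    """Institutional features of a game for a given focal player."""

    stable: bool
    predictable: bool
    efficient: bool

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (self.stable, self.predictable, self.efficient)


@lru_cache(maxsize=16384)
def _features_cached(game: OrdinalGame, focal: int) -> FeatureVector:
    mask = pure_nash_mask(game)
    n_pure = int(mask.sum())
    # some pure equilibrium outcome pays the focal player the top rank
    efficient = bool(np.any(mask & (game.ranks[:, focal] == game.max_rank)))
    if game.n_players == 2:
        # the mixed equilibrium exists exactly when the pure count != 1
        total = n_pure + (0 if n_pure == 1 else 1)
        stable = total == 1
    else:
        stable = n_pure == 1
    return FeatureVector(stable=stable, predictable=n_pure == 1, efficient=efficient)


def game_features(game: OrdinalGame, focal: int) -> FeatureVector:
    """Evaluate (stable, predictable, efficient) for ``focal``."""
    if not 0 <= focal < game.n_players:
        raise ValueError(f"focal player {focal} out of range for {game.n_players} players")
    return _features_cached(game, focal)


def is_attractor(game: OrdinalGame, focal: int) -> bool:
    """True iff the game has a unique pure equilibrium paying ``focal`` 2**n.

    Needs only pure enumeration, so it works for any number of players.
    """
    mask = pure_nash_mask(game)
    if int(mask.sum()) != 1:
        return False
    o = int(np.flatnonzero(mask)[0])
    return int(game.ranks[o, focal]) == game.max_rank


def prefer(feature_a: FeatureVector, feature_b: FeatureVector) -> int:
    """Lexicographic comparison (stable > predictable > efficient).

    Returns 1 if ``feature_a`` is strictly preferred, -1 if
    ``feature_b`` is, and 0 for indifference.  Indifference between
    attractor games is what makes basins neutral.
    """
    a, b = feature_a.as_tuple(), feature_b.as_tuple()
    return (a > b) - (a < b)


def choose_next(
    game: OrdinalGame, focal: int, rng: np.random.Generator
) -> Optional[OrdinalGame]:
    """One hill-climbing step: a uniformly chosen best strictly-preferred neighbour.

    Returns ``None`` when no neighbour is strictly preferred to the
    current game — i.e. the game is a local terminus of the dynamic.
    """
    current = game_features(game, focal).as_tuple()
    tier_key = None
    tier: list[OrdinalGame] = []
    for h in neighbors(game):
        key = game_features(h, focal).as_tuple()
        if key <= current:
            continue
        if tier_key is None or key > tier_key:
            tier_key, tier = key, [h]
        elif key == tier_key:
            tier.append(h)
    if not tier:
        return None
    return tier[int(rng.integers(len(tier)))]


def _drift_path(
    game: OrdinalGame, focal: int, rng: np.random.Generator
) -> Optional[list[OrdinalGame]]:
    """Shortest neutral path to a plateau game with a strict improvement.

    BFS over neighbours with *equal* features (moves the agent is
    indifferent about).  Among the nearest plateau games that have a
    strictly preferred neighbour, one is chosen uniformly at random and
    the path to it (excluding ``game`` itself) is returned.  ``None``
    means the whole plateau component is exitless — the trajectory has
    reached a basin.
    """
    current = game_features(game, focal).as_tuple()
    parent: dict[OrdinalGame, Optional[OrdinalGame]] = {game: None}
    frontier = [game]
    while frontier:
        exits = []
        next_frontier = []
        for g in frontier:
            for h in neighbors(g):
                if h in parent:
                    continue
                key = game_features(h, focal).as_tuple()
                if key == current:
                    parent[h] = g
                    next_frontier.append(h)
        for g in next_frontier:
            if any(
                game_features(h, focal).as_tuple() > current for h in neighbors(g)
            ):
                exits.append(g)
        if exits:
            target = exits[int(rng.integers(len(exits)))]
            path = [target]
            while parent[path[-1]] is not game:
                path.append(parent[path[-1]])
            path.reverse()
            return path
        frontier = next_frontier
    return None


@dataclass
class TrajectoryRecord:
    """One simulation run: the games visited and who drove the moves."""

    games: list[OrdinalGame]
    focal: int
    first_game_earnings: PlayResult
    terminated: bool
    steps: int
    seed: Optional[int]


def run_trajectory(
    start: OrdinalGame,
    seed: Optional[int] = None,
    max_steps: int = 1000,
    *,
    rng: Optional[np.random.Generator] = None,
    focal: Optional[int] = None,
) -> TrajectoryRecord:
    """Simulate one institutional-evolution run from ``start``.

    The start game is played; the player with strictly greater earnings
    becomes focal (first-game ties break uniformly at random) and keeps
    control for the whole run.  The trajectory then follows
    :func:`choose_next`; when no neighbour is strictly preferred it
    drifts along neutral (equal-feature) moves toward the nearest
    plateau game with a strict improvement, and terminates
    (``terminated=True``) only when the plateau has none — i.e. in a
    basin.  ``terminated=False`` means ``max_steps`` was exhausted.

    ``focal`` may be forced for controlled experiments; the first game
    is still played so earnings are recorded either way.  Only
    two-player trajectories are supported.
    """
    if start.n_players != 2:
        raise UnsupportedGameError("trajectories are exercised on the two-player space only")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    current = canonicalize(start)
    first_play = play_game(current, rng)
    if focal is None:
        earnings = np.asarray(first_play.earnings)
        best = np.flatnonzero(earnings == earnings.max())
        focal = int(best[0]) if len(best) == 1 else int(best[int(rng.integers(len(best)))])

    games = [current]
    terminated = False
    pending: list[OrdinalGame] = []
    while len(games) - 1 < max_steps:
        if pending:
            current = pending.pop(0)
            games.append(current)
            continue
        nxt = choose_next(current, focal, rng)
        if nxt is not None:
            current = nxt
            games.append(current)
            continue
        path = _drift_path(current, focal, rng)
        if path is None:
            terminated = True
            break
        pending = path
    else:
        terminated = not pending and choose_next(current, focal, rng) is None and _drift_path(
            current, focal, rng
        ) is None

    return TrajectoryRecord(
        games=games,
        focal=focal,
        first_game_earnings=first_play,
        terminated=terminated,
        steps=len(games) - 1,
        seed=seed,
    )


@dataclass
class AttractorReport:
    """The attractor games for a focal player and their basin structure."""

    focal: int
    attractors: list[OrdinalGame]
    basin_components: list[set[OrdinalGame]] = field(default_factory=list)


def attractor_set(space: Sequence[OrdinalGame], focal: int) -> AttractorReport:
    """Filter ``space`` by :func:`is_attractor` and split into contiguous basins.

    Components are connected components of the attractor set under the
    neighbour relation.
    """
    attractors = [g for g in space if is_attractor(g, focal)]
    members = set(attractors)
    graph = nx.Graph()
    graph.add_nodes_from(attractors)
    for g in attractors:
        for h in neighbors(g):
            if h in members:
                graph.add_edge(g, h)
    components = [set(c) for c in nx.connected_components(graph)]
    return AttractorReport(focal=focal, attractors=attractors, basin_components=components)


def attractor_counts(space: Sequence[OrdinalGame]) -> dict[str, int]:
    """Attractor counts under each focal-player convention.

    Reported for transparency: the space distinguishes row and column,
    so the census is quoted for a fixed focal player (row), but the
    per-focal, either-focal and both-focal counts are all recorded.
    """
    a0 = {g for g in space if is_attractor(g, 0)}
    a1 = {g for g in space if is_attractor(g, 1)}
    return {
        "focal0": len(a0),
        "focal1": len(a1),
        "either": len(a0 | a1),
        "both": len(a0 & a1),
    }


def neighbor_graph(space: Sequence[OrdinalGame]) -> nx.Graph:
    """The undirected neighbour graph over a set of canonical games."""
    graph = nx.Graph()
    graph.add_nodes_from(space)
    members = set(space)
    for g in space:
        for h in neighbors(g):
            if h in members:
                graph.add_edge(g, h)
    return graph


def graph_distance(g: OrdinalGame, h: OrdinalGame) -> int:
    """Minimum number of swaps separating two games (BFS shortest path)."""
    a, b = canonicalize(g), canonicalize(h)
    if a == b:
        return 0
    dist = {a: 0}
    queue = deque([a])
    while queue:
        cur = queue.popleft()
        for nxt in neighbors(cur):
            if nxt in dist:
                continue
            dist[nxt] = dist[cur] + 1
            if nxt == b:
                return dist[nxt]
            queue.append(nxt)
    raise InvariantError("neighbour graph is not connected between the given games")
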