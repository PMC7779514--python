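"""Two-choice ordinal games and the space they live in.

An *ordinal game* on ``n`` players gives each player a strict ranking
(1 = worst, 2**n = best) of the 2**n joint-choice outcomes.  Outcomes are
enumerated as integers ``0 .. 2**n - 1`` whose binary expansion lists the
players' choices with **player 0 as the most significant bit**, so for two
players the order is (0,0), (0,1), (1,0), (1,1).

Two payoff tables describe the same game when they differ only by flipping
the labels of some player's own two choices.  Each such relabeling XORs the
outcome index with the moving players' bit mask; the group has 2**n elements
and acts freely on strict tables, so every orbit has exactly 2**n members.
The *canonical form* of a game is the orbit member whose flattened rank
table is lexicographically smallest.

The edge structure of the space is generated by :class:`SwapMove`: one
player exchanges the outcomes holding two adjacently ranked payoffs
(k and k+1).  Two canonical games are *neighbours* if a single swap maps
one onto (a relabeling of) the other.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GameError",
    "InvariantError",
    "OrdinalGame",
    "SwapMove",
    "make_game",
    "canonicalize",
    "enumerate_two_player_space",
    "count_games",
    "sample_game",
    "apply_swap",
    "neighbors",
    "is_win_win",
    "outcome_choices",
    "choices_to_index",
    "game_to_dict",
    "game_from_dict",
    "game_to_json",
    "game_from_json",
]


class GameError(ValueError):
    """An invalid game description (ties, missing outcomes, bad ranks)."""


class InvariantError(RuntimeError):
    """A structural invariant of the game space failed to hold."""


def player_bit(player: int, n_players: int) -> int:
    """Bit mask of ``player`` in the outcome index (player 0 = MSB)."""
    return 1 << (n_players - 1 - player)


def outcome_choices(index: int, n_players: int) -> tuple[int, ...]:
    """Decode an outcome index into the profile of binary choices."""
    return tuple((index >> (n_players - 1 - j)) & 1 for j in range(n_players))


def choices_to_index(choices: Sequence[int]) -> int:
    """Encode a profile of binary choices as an outcome index."""
    index = 0
    for c in choices:
        index = (index << 1) | (c & 1)
    return index


class OrdinalGame:
    """An n-player two-choice game with strict ordinal payoffs.

    Parameters
    ----------
    n_players
        Number of players (>= 1).
    ranks
        Array of shape ``(2**n_players, n_players)``; ``ranks[o, j]`` is
        player ``j``'s rank of outcome ``o`` (1 = worst, 2**n = best).
        Each column must be a permutation of ``1 .. 2**n`` — strict
        rankings admit no ties.

    Instances are immutable and hashable, so they can key caches and sets.
    """

    __slots__ = ("n_players", "ranks", "_key")

    def __init__(self, n_players: int, ranks: np.ndarray, *, validate: bool = True):
        ranks = np.asarray(ranks, dtype=np.int64)
        if validate:
            _validate_table(n_players, ranks)
        ranks = ranks.copy()
        ranks.setflags(write=False)
        object.__setattr__(self, "n_players", int(n_players))
        object.__setattr__(self, "ranks", ranks)
        object.__setattr__(self, "_key", None)

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("OrdinalGame is immutable")

    @property
    def n_outcomes(self) -> int:
        return 1 << self.n_players

    @property
    def max_rank(self) -> int:
        return 1 << self.n_players

    def key(self) -> tuple[int, ...]:
        """Flattened rank table (outcome-major); the serialization order."""
        k = object.__getattribute__(self, "_key")
        if k is None:
            k = tuple(int(x) for x in self.ranks.ravel())
            object.__setattr__(self, "_key", k)
        return k

    def payoffs(self, outcome: int | Sequence[int]) -> tuple[int, ...]:
        """Payoff vector of an outcome given by index or choice profile."""
        if not isinstance(outcome, (int, np.integer)):
            outcome = choices_to_index(outcome)
        return tuple(int(x) for x in self.ranks[outcome])

    def __eq__(self, other):
        return (
            isinstance(other, OrdinalGame)
            and self.n_players == other.n_players
            and self.key() == other.key()
        )

    def __hash__(self):
        return hash((self.n_players, self.key()))

    def __repr__(self):
        return f"OrdinalGame(n_players={self.n_players}, ranks={self.ranks.tolist()})"


def _validate_table(n_players: int, ranks: np.ndarray) -> None:
    if n_players < 1:
        raise GameError(f"need at least one player, got {n_players}")
    m = 1 << n_players
    if ranks.ndim != 2 or ranks.shape != (m, n_players):
        raise GameError(
            f"rank table must have shape ({m}, {n_players}) "
            f"for {n_players} players, got {ranks.shape}"
        )
    expected = np.arange(1, m + 1)
    for j in range(n_players):
        col = np.sort(ranks[:, j])
        if not np.array_equal(col, expected):
            raise GameError(
                f"player {j} ranks must be a permutation of 1..{m} "
                f"(strict ordinal ranking, no ties); got {sorted(ranks[:, j].tolist())}"
            )


@dataclass(frozen=True)
class SwapMove:
    """One player's exchange of the outcomes holding ranks k and k+1.

    ``low_rank`` is k, with ``1 <= k <= 2**n - 1``.  Applying the same
    move twice restores the original game.
    """

    player: int
    low_rank: int


def make_game(
    n_players: int,
    rank_table: Mapping[tuple[int, ...], Sequence[int]] | Sequence[Sequence[int]] | np.ndarray,
) -> OrdinalGame:
    """Build a validated :class:`OrdinalGame` from a rank table.

    ``rank_table`` is either a mapping from choice profiles (tuples of 0/1)
    to payoff vectors, or a nested sequence / array indexed
    ``[outcome][player]`` in the documented outcome order.

    Raises
    ------
    GameError
        If any outcome is missing or duplicated, or a player's ranks are
        not a permutation of ``1 .. 2**n`` (ties or out-of-range values).
    """
    m = 1 << n_players
    if isinstance(rank_table, Mapping):
        arr = np.zeros((m, n_players), dtype=np.int64)
        seen: set[int] = set()
        for profile, payoffs in rank_table.items():
            profile = tuple(profile)
            if len(profile) != n_players or any(c not in (0, 1) for c in profile):
                raise GameError(f"bad choice profile {profile!r} for {n_players} players")
            idx = choices_to_index(profile)
            if idx in seen:
                raise GameError(f"duplicate outcome {profile!r}")
            seen.add(idx)
            arr[idx] = np.asarray(payoffs, dtype=np.int64)
        if len(seen) != m:
            missing = [outcome_choices(i, n_players) for i in range(m) if i not in seen]
            raise GameError(f"missing outcomes: {missing}")
    else:
        arr = np.asarray(rank_table, dtype=np.int64)
    return OrdinalGame(n_players, arr)


# ---------------------------------------------------------------------------
# Symmetry and canonical forms


@lru_cache(maxsize=32)
def _relabel_index(n_players: int, mask: int) -> np.ndarray:
    """Outcome permutation induced by flipping the choice labels in ``mask``."""
    return np.arange(1 << n_players) ^ mask


def relabel(game: OrdinalGame, mask: int) -> OrdinalGame:
    """Flip the choice labels of every player whose bit is set in ``mask``."""
    perm = _relabel_index(game.n_players, mask)
    return OrdinalGame(game.n_players, game.ranks[perm], validate=False)


def canonicalize(game: OrdinalGame) -> OrdinalGame:
    """Return the canonical representative of the game's relabeling orbit.

    The representative is the orbit member with the lexicographically
    smallest flattened rank table.  Idempotent; the orbit has exactly
    ``2**n_players`` members because the action is free on strict tables.
    """
    n = game.n_players
    best = None
    best_key = None
    for mask in range(1 << n):
        cand = game.ranks[_relabel_index(n, mask)]
        key = tuple(int(x) for x in cand.ravel())
        if best_key is None or key < best_key:
            best_key = key
            best = cand
    return OrdinalGame(n, best, validate=False)


def orbit(game: OrdinalGame) -> list[OrdinalGame]:
    """All distinct relabelings of ``game`` (its symmetry orbit)."""
    seen = {}
    for mask in range(1 << game.n_players):
        g = relabel(game, mask)
        seen[g.key()] = g
    return list(seen.values())


def enumerate_two_player_space() -> list[OrdinalGame]:
    """All canonical two-player games, sorted by serialized rank table.

    The 576 raw tables (24 row permutations x 24 column permutations)
    collapse to 144 canonical games under per-player choice relabeling.
    """
    perms = list(itertools.permutations(range(1, 5)))
    seen: dict[tuple[int, ...], OrdinalGame] = {}
    for row in perms:
        for col in perms:
            ranks = np.column_stack([row, col])
            g = canonicalize(OrdinalGame(2, ranks, validate=False))
            seen[g.key()] = g
    return [seen[k] for k in sorted(seen)]


def count_games(n_players: int) -> int:
    """Exact number of canonical n-player two-choice ordinal games.

    Each of the n players independently assigns a permutation of
    ``1 .. 2**n`` to the outcomes, giving ``((2**n)!)**n`` raw tables;
    the free choice-relabeling group of order ``2**n`` removes the
    double counting:  ``((2**n)!)**n // 2**n``.  Evaluated in exact
    integer arithmetic.
    """
    if n_players < 1:
        raise GameError(f"need at least one player, got {n_players}")
    m = 1 << n_players
    return math.factorial(m) ** n_players // m


def sample_game(n_players: int, rng: np.random.Generator) -> OrdinalGame:
    """Draw a uniformly random raw ordinal game.

    Each player's ranks are an independent uniform permutation of
    ``1 .. 2**n`` over the outcomes.  Because the relabeling action is
    free, this also induces the uniform distribution over canonical
    games; the table is *not* canonicalized here.
    """
    m = 1 << n_players
    ranks = np.empty((m, n_players), dtype=np.int64)
    for j in range(n_players):
        ranks[:, j] = rng.permutation(m) + 1
    return OrdinalGame(n_players, ranks, validate=False)


# ---------------------------------------------------------------------------
# Moves and adjacency


def apply_swap(game: OrdinalGame, move: SwapMove) -> OrdinalGame:
    """Exchange the outcomes holding ranks k and k+1 for one player."""
    n = game.n_players
    if not 0 <= move.player < n:
        raise GameError(f"player index {move.player} out of range for {n} players")
    if not 1 <= move.low_rank <= game.max_rank - 1:
        raise GameError(f"low_rank {move.low_rank} out of range 1..{game.max_rank - 1}")
    col = game.ranks[:, move.player]
    i = int(np.flatnonzero(col == move.low_rank)[0])
    j = int(np.flatnonzero(col == move.low_rank + 1)[0])
    ranks = game.ranks.copy()
    ranks[i, move.player], ranks[j, move.player] = move.low_rank + 1, move.low_rank
    return OrdinalGame(n, ranks, validate=False)


def all_moves(game: OrdinalGame) -> list[SwapMove]:
    """The n x (2**n - 1) adjacent-rank swaps available from ``game``."""
    return [
        SwapMove(player=j, low_rank=k)
        for j in range(game.n_players)
        for k in range(1, game.max_rank)
    ]


@lru_cache(maxsize=8192)
def _neighbors_cached(game: OrdinalGame) -> tuple[OrdinalGame, ...]:
    self_c = canonicalize(game)
    seen: dict[tuple[int, ...], OrdinalGame] = {}
    for move in all_moves(game):
        h = canonicalize(apply_swap(game, move))
        if h != self_c:
            seen[h.key()] = h
    return tuple(seen[k] for k in sorted(seen))


def neighbors(game: OrdinalGame) -> list[OrdinalGame]:
    """Distinct canonical games one swap away from ``game``.

    Generates every single-swap variant, canonicalizes, and removes
    duplicates and the game's own canonical form.  The relation is
    symmetric because swaps are involutions and relabelings commute
    with them.
    """
    return list(_neighbors_cached(game))


def is_win_win(game: OrdinalGame) -> bool:
    """True iff some outcome carries every player's top rank ``2**n``."""
    return bool(np.any(np.all(game.ranks == game.max_rank, axis=1)))


# ---------------------------------------------------------------------------
# Serialization: JSON records {"n_players": n, "ranks": [[...], ...]}
# with ranks indexed [outcome][player] in the documented outcome order.


def game_to_dict(game: OrdinalGame) -> dict:
    return {"n_players": game.n_players, "ranks": game.ranks.tolist()}


def game_from_dict(record: Mapping) -> OrdinalGame:
    try:
        n = int(record["n_players"])
        ranks = record["ranks"]
    except (KeyError, TypeError) as exc:
        raise GameError(f"malformed game record: {record!r}") from exc
    return make_game(n, ranks)


def game_to_json(game: OrdinalGame) -> str:
    return json.dumps(game_to_dict(game), separators=(",", ":"))


def game_from_json(text: str) -> OrdinalGame:
    return game_from_dict(json.loads(text))
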