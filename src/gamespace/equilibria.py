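"""Nash equilibria of two-choice ordinal games, and within-game play.

Pure-strategy equilibria are found by the unilateral-deviation check:
with two choices per player there is exactly one deviation per player
per outcome, so outcome ``o`` is an equilibrium iff every player ranks
``o`` above the outcome reached by flipping their own bit.  Strict
rankings make every comparison decisive.

For two-player games with no pure equilibrium, the unique fully mixed
equilibrium follows from the closed-form indifference conditions (each
player's mixture makes the *opponent* indifferent between their two
choices), with ranks treated as cardinal utilities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np

from .games import OrdinalGame, choices_to_index, outcome_choices

__all__ = [
    "Outcome",
    "StrategyProfile",
    "EquilibriumSet",
    "PlayResult",
    "UnsupportedGameError",
    "pure_nash",
    "pure_nash_count",
    "mixed_equilibrium_2x2",
    "equilibrium_set",
    "play_game",
    "nash_count_histogram",
]

#: An outcome is a profile of binary choices, one per player.
Outcome = tuple[int, ...]


class UnsupportedGameError(RuntimeError):
    """Raised for game classes outside the implemented scope (mixed n > 2)."""


@dataclass(frozen=True)
class StrategyProfile:
    """Per-player probability of playing choice 1.

    At a fully mixed 2x2 equilibrium both probabilities lie strictly in
    (0, 1) and each makes the opponent indifferent between choices.
    """

    p_choice1: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.p_choice1)


@dataclass(frozen=True)
class MixedEquilibrium:
    profile: StrategyProfile
    expected_payoffs: tuple[float, ...]


@dataclass(frozen=True)
class EquilibriumSet:
    """Pure Nash outcomes plus, for 2-player games without one, the mixed equilibrium."""

    pure: tuple[Outcome, ...]
    mixed: Optional[MixedEquilibrium]

    @property
    def total_count(self) -> int:
        return len(self.pure) + (1 if self.mixed is not None else 0)


@dataclass(frozen=True)
class PlayResult:
    """Earnings of one play of a game.

    ``realized_outcome`` is set for pure-equilibrium play; mixed play
    reports expected payoffs and no realized outcome.
    """

    earnings: tuple[float, ...]
    realized_outcome: Optional[Outcome]


@lru_cache(maxsize=32)
def _deviation_index(n_players: int) -> np.ndarray:
    """``dev[j, o]`` = outcome reached from ``o`` when player j flips."""
    m = 1 << n_players
    o = np.arange(m)
    return np.stack([o ^ (1 << (n_players - 1 - j)) for j in range(n_players)])


def pure_nash_mask(game: OrdinalGame) -> np.ndarray:
    """Boolean array over outcome indices marking pure Nash equilibria."""
    ranks = game.ranks
    dev = _deviation_index(game.n_players)
    ok = np.ones(game.n_outcomes, dtype=bool)
    for j in range(game.n_players):
        ok &= ranks[:, j] > ranks[dev[j], j]
    return ok


def pure_nash(game: OrdinalGame) -> list[Outcome]:
    """Pure-strategy Nash equilibria, as choice profiles in outcome order."""
    n = game.n_players
    return [outcome_choices(int(o), n) for o in np.flatnonzero(pure_nash_mask(game))]


def pure_nash_count(game: OrdinalGame) -> int:
    """Number of pure-strategy Nash equilibria (cheap path for censuses)."""
    return int(pure_nash_mask(game).sum())


def mixed_equilibrium_2x2(game: OrdinalGame) -> MixedEquilibrium:
    """The unique fully mixed equilibrium of a 2x2 game with no pure one.

    Writing u_r / u_c for row's and column's cardinalized ranks, column's
    probability q of choice 1 solves row's indifference
    ``(1-q) u_r(0,0) + q u_r(0,1) = (1-q) u_r(1,0) + q u_r(1,1)``, and
    symmetrically for row's probability p.  For strict ordinal payoffs
    with no pure equilibrium both denominators are nonzero and both
    probabilities land strictly inside (0, 1).

    Raises
    ------
    UnsupportedGameError
        If the game is not two-player.
    ValueError
        If the game has a pure equilibrium (callers must use pure play),
        or — signalling an upstream bug — a degenerate indifference
        denominator.
    """
    if game.n_players != 2:
        raise UnsupportedGameError("closed-form mixed equilibria implemented for 2 players only")
    if pure_nash_count(game) > 0:
        raise ValueError("game has a pure equilibrium; mixed play does not apply")
    u = game.ranks.astype(float)  # rows: outcomes (0,0),(0,1),(1,0),(1,1)
    u_r = {(r, c): u[2 * r + c, 0] for r in (0, 1) for c in (0, 1)}
    u_c = {(r, c): u[2 * r + c, 1] for r in (0, 1) for c in (0, 1)}

    den_q = (u_r[0, 0] - u_r[1, 0]) + (u_r[1, 1] - u_r[0, 1])
    den_p = (u_c[0, 0] - u_c[0, 1]) + (u_c[1, 1] - u_c[1, 0])
    if abs(den_q) < 1e-12 or abs(den_p) < 1e-12:
        raise ValueError("degenerate indifference condition; not a strict no-pure-Nash game")
    q = (u_r[0, 0] - u_r[1, 0]) / den_q  # column's probability of choice 1
    p = (u_c[0, 0] - u_c[0, 1]) / den_p  # row's probability of choice 1

    probs = np.array([(1 - p) * (1 - q), (1 - p) * q, p * (1 - q), p * q])
    expected = probs @ u
    return MixedEquilibrium(
        profile=StrategyProfile(p_choice1=(float(p), float(q))),
        expected_payoffs=tuple(float(x) for x in expected),
    )


def equilibrium_set(game: OrdinalGame) -> EquilibriumSet:
    """Pure equilibria plus, for 2-player games lacking one, the mixed equilibrium."""
    pure = tuple(pure_nash(game))
    mixed = None
    if not pure and game.n_players == 2:
        mixed = mixed_equilibrium_2x2(game)
    return EquilibriumSet(pure=pure, mixed=mixed)


def play_game(game: OrdinalGame, rng: np.random.Generator) -> PlayResult:
    """Play a game under equilibrium rationality.

    A unique pure equilibrium is played deterministically; with several
    pure equilibria one is drawn uniformly at random; with none (2-player
    only) the players mix, and the *expected* payoffs of the mixed
    equilibrium are returned so that mixed play is deterministic.
    """
    pure = pure_nash(game)
    if len(pure) == 1:
        outcome = pure[0]
    elif pure:
        outcome = pure[int(rng.integers(len(pure)))]
    else:
        if game.n_players != 2:
            raise UnsupportedGameError(
                "no pure equilibrium and mixed play is implemented for 2 players only"
            )
        mixed = mixed_equilibrium_2x2(game)
        return PlayResult(earnings=mixed.expected_payoffs, realized_outcome=None)
    payoffs = game.payoffs(choices_to_index(outcome))
    return PlayResult(earnings=tuple(float(x) for x in payoffs), realized_outcome=outcome)


def nash_count_histogram(games: Iterable[OrdinalGame]) -> dict[int, float]:
    """Frequency distribution of pure-equilibrium counts over ``games``."""
    counts = Counter(pure_nash_count(g) for g in games)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: counts[k] / total for k in sorted(counts)}
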