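"""Equality and scaling measures over game spaces.

Two measures of how fair a game's equilibria are:

* the proportion of *win–win* games — games with an outcome paying every
  player their top rank, which happens with probability ``2**(n - n**2)``
  for a uniformly random n-player game (the 2**n outcomes are disjoint
  candidates, each all-top with probability ``2**(-n*n)``);
* the Gini coefficient of equilibrium payoffs,
  ``G = sum_ij |x_i - x_j| / (2 n^2 mean(x))``, zero when all players
  earn the same and approaching 1 under extreme dispersion.

Monte-Carlo estimators sample uniformly random games (seeded, hence
exactly reproducible) to trace how the attractor fraction, the
equilibrium-count distribution and the fairness gap between attractors
and the bulk of the space scale with the number of players.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import is_attractor
from .equilibria import pure_nash_count, pure_nash_mask
from .games import OrdinalGame, is_win_win, sample_game

__all__ = [
    "SampleEstimate",
    "GiniComparison",
    "gini",
    "equilibrium_gini",
    "win_win_fraction",
    "estimate_attractor_fraction",
    "estimate_win_win_fraction",
    "estimate_equilibrium_count_distribution",
    "compare_equilibrium_gini",
]


@dataclass(frozen=True)
class SampleEstimate:
    """A seeded Monte-Carlo estimate of a game-space property."""

    mean: float
    std_error: float
    n_samples: int
    seed: Optional[int]
    n_players: int


def gini(payoffs) -> float:
    """Gini coefficient ``sum_ij |x_i - x_j| / (2 n^2 mean)`` of a payoff vector.

    Scale-invariant; 0 iff all payoffs are equal; always < 1 for
    positive payoffs.
    """
    x = np.asarray(payoffs, dtype=float)
    if x.size == 0:
        raise ValueError("gini requires at least one payoff")
    if np.any(x <= 0):
        raise ValueError("gini requires positive payoffs")
    n = x.size
    abs_diff = np.abs(x[:, None] - x[None, :]).sum()
    return float(abs_diff / (2 * n * n * x.mean()))


def equilibrium_gini(game: OrdinalGame) -> Optional[float]:
    """Mean Gini over the payoff vectors of a game's pure Nash outcomes.

    ``None`` when the game has no pure equilibrium (its equilibrium
    payoffs would require mixed expectations, which are excluded from
    the fairness comparison).
    """
    mask = pure_nash_mask(game)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    return float(np.mean([gini(game.ranks[int(o)]) for o in idx]))


def win_win_fraction(n_players: int) -> float:
    """Closed-form probability that a uniform random game is win–win.

    Each player's top rank sits at one uniform outcome, independently
    across players, so a fixed outcome is all-top with probability
    ``(2**-n)**n``; the 2**n candidate outcomes are mutually exclusive,
    giving ``2**(n - n**2)``.
    """
    if n_players < 1:
        raise ValueError("need at least one player")
    return float(2.0 ** (n_players - n_players * n_players))


def _proportion_estimate(
    hits: int, n_samples: int, seed: Optional[int], n_players: int
) -> SampleEstimate:
    p = hits / n_samples
    se = float(np.sqrt(p * (1 - p) / n_samples))
    return SampleEstimate(
        mean=p, std_error=se, n_samples=n_samples, seed=seed, n_players=n_players
    )


def estimate_attractor_fraction(
    n_players: int, n_samples: int, seed: int, focal: int = 0
) -> SampleEstimate:
    """Monte-Carlo fraction of random n-player games that are attractors."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    hits = sum(
        is_attractor(sample_game(n_players, rng), focal) for _ in range(n_samples)
    )
    return _proportion_estimate(hits, n_samples, seed, n_players)


def estimate_win_win_fraction(n_players: int, n_samples: int, seed: int) -> SampleEstimate:
    """Monte-Carlo win–win frequency; converges to :func:`win_win_fraction`."""
    rng = np.random.default_rng(seed)
    hits = sum(is_win_win(sample_game(n_players, rng)) for _ in range(n_samples))
    return _proportion_estimate(hits, n_samples, seed, n_players)


def estimate_equilibrium_count_distribution(
    n_players: int, n_samples: int, seed: int
) -> dict[int, SampleEstimate]:
    """Sampled distribution of pure-equilibrium counts per game.

    As the number of players grows the distribution approaches Poisson
    with unit mean: about ``e**-1 ~ 37%`` of games have zero pure
    equilibria, the same fraction exactly one, and roughly a quarter
    have two or more.
    """
    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    for _ in range(n_samples):
        c = pure_nash_count(sample_game(n_players, rng))
        counts[c] = counts.get(c, 0) + 1
    return {
        k: _proportion_estimate(v, n_samples, seed, n_players)
        for k, v in sorted(counts.items())
    }


@dataclass(frozen=True)
class GiniComparison:
    """Mean equilibrium Gini of all games vs attractor games.

    ``difference`` is all-games mean minus attractor mean: positive when
    attractors are the fairer subset.  ``n_excluded_no_pure`` counts
    sampled games dropped for lacking a pure equilibrium;
    ``n_extra_draws`` counts rejection-sampling draws beyond the base
    sample used to top up rare attractors.
    """

    all_games: SampleEstimate
    attractors: SampleEstimate
    difference: float
    difference_se: float
    n_excluded_no_pure: int
    n_extra_draws: int


def _mean_estimate(
    values: list[float], seed: Optional[int], n_players: int
) -> SampleEstimate:
    arr = np.asarray(values, dtype=float)
    k = arr.size
    mean = float(arr.mean()) if k else float("nan")
    se = float(arr.std(ddof=1) / np.sqrt(k)) if k > 1 else float("nan")
    return SampleEstimate(mean=mean, std_error=se, n_samples=k, seed=seed, n_players=n_players)


def compare_equilibrium_gini(
    n_players: int,
    n_samples: int,
    seed: int,
    focal: int = 0,
    min_attractor_samples: int = 30,
    max_extra_draws: int = 500_000,
) -> GiniComparison:
    """Fairness gap between the whole space and its attractors.

    Draws ``n_samples`` random games; averages :func:`equilibrium_gini`
    over (a) every sampled game with at least one pure equilibrium and
    (b) the sampled attractor games.  Attractors become rare at large n,
    so when fewer than ``min_attractor_samples`` turn up, extra games
    are rejection-sampled (up to ``max_extra_draws``) solely to top up
    the attractor average; a warning is issued if the floor still is
    not met.  Standard error of the difference is propagated in
    quadrature.
    """
    rng = np.random.default_rng(seed)
    all_ginis: list[float] = []
    attractor_ginis: list[float] = []
    excluded = 0
    for _ in range(n_samples):
        g = sample_game(n_players, rng)
        value = equilibrium_gini(g)
        if value is None:
            excluded += 1
            continue
        all_ginis.append(value)
        if is_attractor(g, focal):
            attractor_ginis.append(value)

    extra = 0
    while len(attractor_ginis) < min_attractor_samples and extra < max_extra_draws:
        g = sample_game(n_players, rng)
        extra += 1
        if is_attractor(g, focal):
            attractor_ginis.append(equilibrium_gini(g))
    if len(attractor_ginis) < min_attractor_samples:
        warnings.warn(
            f"only {len(attractor_ginis)} attractor samples obtained for "
            f"n={n_players} after {n_samples + extra} draws",
            stacklevel=2,
        )

    est_all = _mean_estimate(all_ginis, seed, n_players)
    est_att = _mean_estimate(attractor_ginis, seed, n_players)
    diff = est_all.mean - est_att.mean
    diff_se = float(np.hypot(est_all.std_error, est_att.std_error))
    return GiniComparison(
        all_games=est_all,
        attractors=est_att,
        difference=diff,
        difference_se=diff_se,
        n_excluded_no_pure=excluded,
        n_extra_draws=extra,
    )
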