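# Methods

## Games and their representation

A game has `n` players, two choices per player, and 2^n outcomes.  An
outcome is a profile of binary choices, stored as the integer whose
binary expansion lists the choices with player 0 as the most
significant bit; for two players the order is (0,0), (0,1), (1,0),
(1,1).  Payoffs are strict ordinal ranks: each player's column of the
`(2^n, n)` rank table is a permutation of 1..2^n, validated at
construction.  Where arithmetic is unavoidable — mixed-strategy
expectations, earnings comparisons, Gini — ranks are treated as
cardinal utilities; every exact census result depends only on their
order.

## Symmetry and canonical forms

Flipping a player's own two choice labels permutes outcomes by XOR-ing
the outcome index with that player's bit.  These flips generate a group
of order 2^n acting freely on strict tables (a nontrivial relabeling
always moves some rank), so orbits have exactly 2^n members and the
space contains ((2^n)!)^n / 2^n games, evaluated in exact integer
arithmetic.  The canonical representative of an orbit is the member
whose flattened rank table is lexicographically smallest; any fixed
deterministic choice yields the same censuses.  Player roles are *not*
quotiented: row and column are distinguishable, which is what makes the
two-player space 144 games rather than 78.

Uniform sampling draws an independent uniform permutation of ranks per
player and does not canonicalize; freeness of the group action makes
the induced distribution over canonical games exactly uniform, and the
properties measured on samples (equilibrium counts, win–win, attractor
status) are invariant under relabeling anyway.

## Equilibria

Pure equilibria come from the unilateral-deviation check; with two
choices each player has exactly one deviation per outcome, and strict
rankings make every comparison decisive, so the check is exact integer
comparison with no tolerance.  For two-player games with no pure
equilibrium the unique fully mixed equilibrium is the closed-form
solution of the two indifference equations; its denominators cannot
vanish for a strict table without pure equilibria, and a residual check
at 1e-9 (float noise around an exactly rational solution) guards the
implementation.  Mixed equilibria for n > 2 are out of scope: every
n-player result here needs only pure enumeration.

Within-game play: a unique pure equilibrium is played as is; several
pure equilibria are resolved by a seeded uniform draw; mixed play
returns *expected* payoffs rather than a sampled realization, making
mixed first-game earnings deterministic.  The realized-draw convention
for discrete equilibrium sets and the expectation convention for mixed
play can be compared by replaying with different seeds; only the
first-game winner decision ever consumes this randomness.

## The self-interested dynamic

Game features for a focal player: *stable* means exactly one
equilibrium in total — for n = 2 the mixed equilibrium is counted, and
it exists exactly when the pure count differs from one, so zero pure
equilibria still give a stable (but unpredictable) game while two pure
equilibria give an unstable one; *predictable* means exactly one pure
equilibrium; *efficient* means some pure equilibrium outcome pays the
focal player 2^n (a mixed equilibrium has no outcome and never counts).
For n > 2 stability collapses onto predictability.  Preferences compare
the triple lexicographically (stable > predictable > efficient); ties
are genuine indifference, which is what makes attractor basins neutral.

A trajectory plays the start game, hands control to the strictly
greater earner (first-game ties break uniformly at random), and then
repeats: if any neighbour is strictly preferred, jump to a uniform draw
from the most-preferred tier.  If none is, the agents are indifferent
across the local plateau of equal-feature neighbours, and the
trajectory drifts: a breadth-first search over indifferent moves finds
the nearest plateau games offering a strict improvement, one is chosen
uniformly, and the trajectory walks a shortest plateau path to it.
Termination occurs exactly when the plateau component has no such exit.

The drift step matters.  Under strict-improvement-only hill climbing,
16 two-player games per focal player (12 stable-predictable-
inefficient, 2 stable-only, 2 efficient-only) are local optima that are
not attractors, and the dynamic would terminate at 70 games rather
than the 54-game attractor set.  With neutral drift — which is the
behavioural content of plateau indifference — every plateau below the
top feature class has an exit, verified exhaustively for both focal
players, so the termination set coincides exactly with the attractor
filter (unique pure equilibrium paying the focal player the maximum)
and with its single contiguous basin.  Trajectory length is bounded:
features never decrease, strictly increase at each jump (at most 7
levels), and each drift leg is a shortest path inside a plateau of at
most 144 games; empirically every two-player trajectory terminates
within 3 moves.  `max_steps` defaults to 1000 and exhaustion is
reported via `terminated=False`, never silently truncated.

The attractor census convention is focal = player 0 (row).  Both
conventions give 54; 27 games are attractors for both players and 81
for at least one.  These counts are exported by `attractor_counts` for
transparency.

## Measures and estimators

`gini` implements the pairwise form G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄) over a
game's equilibrium payoff vector, averaged per game when a game has two
pure equilibria.  Games with no pure equilibrium are excluded from
fairness comparisons (their count is reported); the win–win closed form
2^(n−n²) follows from the 2^n mutually exclusive outcomes each being
all-top with probability 2^(−n²).

Monte-Carlo estimators are seeded with `numpy.random.default_rng` and
are exactly reproducible from (n_players, n_samples, seed).  Standard
errors use the normal approximation for proportions and the sample-mean
formula for Gini averages; at the sample sizes used (10^4) these are
adequate and a bootstrap would add nothing.  Attractors become rare as
n grows (fraction ≈ 0.4% at n = 9), so the attractor-vs-all Gini
comparison tops up the attractor sample by rejection sampling beyond
the base draw, up to a cap (default 500,000 draws), and warns when the
configured floor (default 30 attractor samples) is not reached — an
honest sample-size account rather than biased early stopping.

## Problem sizes

The default experiment sizes are those of the study conditions: the
two-player census is exhaustive (no sampling); the dynamics consistency
check runs all 144 starts x 2 focal players x 10 seeds; scaling
experiments use 10,000 games per n for n = 2..9.  The acceptance script
re-runs the exhaustive census and a 10,000-game nine-player equilibrium
census.

## What the generator does and does not emulate

Games are drawn uniformly from the strict-ordinal space, which is the
model's own definition of "random institution" — there is no claim that
real institutions are uniform draws.  Passing tests therefore establish
the combinatorial and dynamical properties of the model space (the
censuses, the Poisson equilibrium limit, the win–win crash, the
vanishing fairness gap), not empirical claims about any observed social
system.  Cardinal treatment of ranks, the single-focal aggregation rule
and the two-choice restriction are all modelling choices inherited with
the framework.

## Known limitations

* Trajectories are implemented for two players only; n-player results
  use feature classification of sampled games, which is all the
  attractor and fairness analyses require.
* Alternative aggregation rules (random dictator, majority) are not
  implemented; `run_trajectory`'s forced-`focal` parameter is the
  extension hook.
* Mixed equilibria are not computed for n > 2, and the Gini of mixed
  expected payoffs is deliberately excluded everywhere.
* The 2-D periodic-table layout sometimes used to draw the two-player
  space is not reproduced; the neighbour graph itself is exported
  instead.
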