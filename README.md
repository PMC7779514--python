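# gamespace

Institutional evolution over the space of two-choice ordinal games.

Many social systems — norms, conventions, resource-management rules —
are better modelled not as a fixed game but as a *trajectory through a
space of games*, reshaped from within by the agents who play them.
`gamespace` implements that framework for the simplest rich setting:
n-player, two-choice normal-form games with strict ordinal payoffs,
where each player ranks the 2^n outcomes 1 (worst) to 2^n (best).  It
is aimed at researchers in evolutionary game theory, cultural evolution
and institutional analysis who want a reproducible simulator for
between-game dynamics.

## The model

* **Space.** Up to per-player relabeling of their own two choices, there
  are ((2^n)!)^n / 2^n distinct games — 144 for n = 2, above 10^50 for
  n = 4.  Two games are *neighbours* when they differ by one player
  swapping the outcomes holding adjacent ranks k and k+1; graph distance
  is the minimum number of such swaps.
* **Within-game behaviour.** Players select the unique pure-strategy
  Nash equilibrium when one exists, randomize uniformly over several,
  and otherwise (two players) play the unique fully mixed equilibrium
  given by the closed-form indifference conditions.
* **Between-game preferences.** A focal player scores whole games by
  three booleans — *stable* (exactly one equilibrium in total),
  *predictable* (exactly one pure equilibrium) and *efficient* (an
  equilibrium outcome pays the focal player the top rank) — compared
  lexicographically in that order.
* **Dynamic.** The winner of the first game becomes focal and
  hill-climbs: move to a uniformly chosen most-preferred strictly
  better neighbour; drift neutrally across equal-feature plateaus when
  no neighbour is strictly better.  Trajectories end in *attractors* —
  games with a unique pure equilibrium paying the focal player the
  maximum — which for n = 2 form a single contiguous, preference-neutral
  basin of 54 games.
* **Measures.** Win–win games (some outcome pays every player the top
  rank) occur with probability 2^(n−n²) in a uniform draw; equilibrium
  fairness is the Gini coefficient G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄) of
  equilibrium payoffs, averaged per game.

The headline two-player result the package reproduces exactly: 36/144
games (25%) are win–win, but 27/54 attractors (50%) are — strictly
self-interested institutional preferences double the concentration of
mutually optimal games, without any preference for fairness.  Monte-
Carlo scaling experiments show the effect vanish as n grows.

## Worked example

```python
>>> import gamespace as gs
>>> space = gs.enumerate_two_player_space()
>>> len(space)
144
>>> report = gs.attractor_set(space, focal=0)
>>> len(report.attractors), len(report.basin_components)
(54, 1)
>>> sum(gs.is_win_win(g) for g in report.attractors)
27
>>> rec = gs.run_trajectory(gs.get_game("prisoners_dilemma"), seed=3)
>>> rec.focal, rec.steps, rec.terminated
(1, 1, True)
>>> gs.is_attractor(rec.games[-1], rec.focal)
True
```

Starting from the Prisoner's Dilemma, player 1 wins the first game (tie
broken randomly at the (2, 2) defection equilibrium), takes control,
and one payoff swap later the trajectory has terminated in an attractor
paying the focal player 4.

The same experiments from the shell:

```sh
gamespace census --out-dir census_out     # prints the counts above, writes CSVs
gamespace trajectory --start prisoners_dilemma --seed 7 --out traj.csv
gamespace scaling --n-min 2 --n-max 9 --samples 10000 --seed 1 --out scaling.csv
gamespace distance --a stag_hunt --b win_win
```

`census` prints `games: 144`, `win-win games: 36`,
`attractors (focal=0): 54`, `basin components (focal=0): 1` and
`win-win attractors (focal=0): 27`; `scaling` writes a tidy CSV of
seeded estimates (attractor fraction, win–win frequency, pure-Nash
count distribution, attractor-vs-all Gini gap) for each n.

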