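{
  "comment": "Named two-player ordinal games. ranks[outcome][player] with outcomes ordered (0,0),(0,1),(1,0),(1,1); player 0 is the row player; 4 = best, 1 = worst.",
  "games": [
    {
      "name": "prisoners_dilemma",
      "n_players": 2,
      "ranks": [[3, 3], [1, 4], [4, 1], [2, 2]],
      "notes": "Unique pure Nash equilibrium at mutual defection (1,1) paying (2,2); not win-win."
    },
    {
      "name": "stag_hunt",
      "n_players": 2,
      "ranks": [[4, 4], [1, 3], [3, 1], [2, 2]],
      "notes": "Two pure equilibria, (0,0) paying (4,4) and (1,1) paying (2,2); win-win but not an attractor."
    },
    {
      "name": "win_win",
      "n_players": 2,
      "ranks": [[4, 4], [2, 3], [3, 1], [1, 2]],
      "notes": "Unique pure equilibrium paying both players 4; one swap away from the Stag Hunt (row's ranks 1 and 2)."
    },
    {
      "name": "chicken",
      "n_players": 2,
      "ranks": [[3, 3], [2, 4], [4, 2], [1, 1]],
      "notes": "Anti-coordination: two pure equilibria at the mismatched outcomes, plus a mixed one."
    },
    {
      "name": "battle_of_the_sexes",
      "n_players": 2,
      "ranks": [[4, 3], [1, 2], [2, 1], [3, 4]],
      "notes": "Coordination with conflicting favourites: two pure equilibria at (0,0) and (1,1)."
    },
    {
      "name": "cyclic",
      "n_players": 2,
      "ranks": [[4, 1], [2, 3], [1, 4], [3, 2]],
      "notes": "Best-response cycle, no pure equilibrium; unique mixed equilibrium with row mixing 1/2 and column playing its first choice with probability 1/4, expected payoffs (2.5, 2.5)."
    }
  ]
}
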