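"""Game construction, symmetry, enumeration, sampling and adjacency."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gamespace as gs
from gamespace.games import all_moves, orbit, relabel


def random_game(n_players: int, seed: int) -> gs.OrdinalGame:
    return gs.sample_game(n_players, np.random.default_rng(seed))


class TestMakeGame:
    def test_mapping_form_matches_sequence_form(self):
        by_map = gs.make_game(
            2, {(0, 0): (3, 3), (0, 1): (1, 4), (1, 0): (4, 1), (1, 1): (2, 2)}
        )
        by_rows = gs.make_game(2, [[3, 3], [1, 4], [4, 1], [2, 2]])
        assert by_map == by_rows

    @pytest.mark.parametrize(
        "table",
        [
            [[1, 3], [1, 4], [3, 1], [2, 2]],  # tie in player 0's ranks
            [[5, 3], [1, 4], [4, 1], [2, 2]],  # out-of-range rank
            [[3, 3], [1, 4], [4, 1]],  # missing outcome
            [[3, 3], [1, 4], [4, 1], [2, 2], [1, 1]],  # extra outcome
        ],
    )
    def test_invalid_tables_rejected(self, table):
        with pytest.raises(gs.GameError):
            gs.make_game(2, table)

    def test_missing_outcome_in_mapping_rejected(self):
        with pytest.raises(gs.GameError, match="missing"):
            gs.make_game(2, {(0, 0): (3, 3), (0, 1): (1, 4), (1, 0): (4, 1)})

    def test_single_player_game_is_legal(self):
        g = gs.make_game(1, [[1], [2]])
        assert g.n_outcomes == 2
        assert gs.is_win_win(g)

    def test_payoff_lookup_by_profile_and_index(self):
        g = gs.make_game(2, [[3, 3], [1, 4], [4, 1], [2, 2]])
        assert g.payoffs((1, 0)) == (4, 1) == g.payoffs(2)


class TestCanonicalize:
    def test_idempotent_on_random_games(self):
        for seed in range(20):
            g = random_game(3, seed)
            c = gs.canonicalize(g)
            assert gs.canonicalize(c) == c

    def test_two_player_orbits_have_size_four(self):
        # free action: all 576 raw tables sit in orbits of exactly 4
        perms = list(itertools.permutations(range(1, 5)))
        for row, col in itertools.product(perms, perms):
            g = gs.make_game(2, np.column_stack([row, col]))
            assert len(orbit(g)) == 4

    def test_relabeling_preserves_canonical_form(self):
        for seed in range(10):
            g = random_game(2, seed)
            for mask in range(4):
                assert gs.canonicalize(relabel(g, mask)) == gs.canonicalize(g)


class TestEnumeration:
    def test_space_has_144_canonical_games(self, space):
        assert len(space) == 144
        assert len(set(space)) == 144

    def test_members_are_their_own_canonical_form(self, space):
        assert all(gs.canonicalize(g) == g for g in space)

    def test_win_win_membership_count(self, space):
        assert sum(gs.is_win_win(g) for g in space) == 36

    def test_catalog_games_are_members(self, space, named):
        members = set(space)
        for name, game in named.items():
            assert gs.canonicalize(game) in members, name


class TestCountGames:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 144)])
    def test_small_counts(self, n, expected):
        assert gs.count_games(n) == expected

    def test_formula_matches_orbit_counting(self):
        # raw tables / orbit size, checked independently of the formula
        assert gs.count_games(2) == 24 * 24 // 4

    def test_four_player_count_is_astronomical(self):
        count = gs.count_games(4)
        assert isinstance(count, int)
        assert count > 10**50

    def test_eight_player_count_exceeds_10_to_4000(self):
        assert gs.count_games(8) > 10**4000


class TestSampling:
    def test_same_seed_same_game(self):
        assert random_game(4, 7) == random_game(4, 7)

    def test_sampled_tables_are_valid(self, rng):
        for n in (1, 2, 5):
            g = gs.sample_game(n, rng)
            gs.make_game(n, g.ranks)  # re-validate

    def test_win_win_frequency_near_one_quarter(self, rng):
        n = 10_000
        hits = sum(gs.is_win_win(gs.sample_game(2, rng)) for _ in range(n))
        p = hits / n
        se = (0.25 * 0.75 / n) ** 0.5
        assert abs(p - 0.25) < 3 * se

    def test_canonical_games_sampled_uniformly(self, space, rng):
        # chi-square over the 144 orbits; free action makes them equiprobable
        from scipy.stats import chisquare

        index = {g: i for i, g in enumerate(space)}
        counts = np.zeros(144)
        n = 10_000
        for _ in range(n):
            counts[index[gs.canonicalize(gs.sample_game(2, rng))]] += 1
        assert chisquare(counts).pvalue > 1e-3


class TestSwapsAndNeighbors:
    @given(seed=st.integers(0, 10**6), player=st.integers(0, 1), low=st.integers(1, 3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_swap_is_an_involution(self, seed, player, low):
        g = random_game(2, seed)
        move = gs.SwapMove(player=player, low_rank=low)
        assert gs.apply_swap(gs.apply_swap(g, move), move) == g

    def test_swap_result_is_valid_permutation(self):
        g = random_game(3, 0)
        for move in all_moves(g):
            h = gs.apply_swap(g, move)
            gs.make_game(3, h.ranks)

    def test_swap_moves_only_the_two_target_ranks(self):
        g = gs.get_game("stag_hunt")
        h = gs.apply_swap(g, gs.SwapMove(player=0, low_rank=1))
        changed = np.flatnonzero(g.ranks[:, 0] != h.ranks[:, 0])
        assert len(changed) == 2
        assert sorted(g.ranks[changed, 0]) == [1, 2]
        assert np.array_equal(g.ranks[:, 1], h.ranks[:, 1])

    def test_stag_hunt_swap_reaches_win_win(self):
        stag = gs.get_game("stag_hunt")
        target = gs.canonicalize(gs.get_game("win_win"))
        swapped = {
            gs.canonicalize(gs.apply_swap(stag, m)) for m in all_moves(stag)
        }
        assert target in swapped

    def test_prisoners_dilemma_has_six_neighbors(self):
        pd = gs.canonicalize(gs.get_game("prisoners_dilemma"))
        assert len(gs.neighbors(pd)) == 6

    def test_raw_move_count_for_two_players(self):
        assert len(all_moves(random_game(2, 1))) == 6

    def test_neighbor_relation_symmetric_and_irreflexive(self, space):
        sample = space[::13]
        for g in sample:
            for h in gs.neighbors(g):
                assert g != h
                assert g in gs.neighbors(h)

    def test_neighbor_graph_connected(self, space):
        import networkx as nx

        assert nx.is_connected(gs.neighbor_graph(space))


class TestWinWin:
    def test_examples(self, named):
        assert gs.is_win_win(named["stag_hunt"])
        assert not gs.is_win_win(named["prisoners_dilemma"])


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self):
        for seed in range(5):
            g = random_game(3, seed)
            assert gs.game_from_json(gs.game_to_json(g)) == g

    def test_malformed_record_rejected(self):
        with pytest.raises(gs.GameError):
            gs.game_from_dict({"ranks": [[1, 2]]})
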