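import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_streaks, strip_break_point_columns, swap_players
from matchmomentum.events import (
    detect_break_points,
    detect_streaks,
    extract_flags,
    flags_to_frame,
    tally_events,
)
from matchmomentum.match_io import MatchRecord, PointRecord


def _match(points):
    return MatchRecord(points[0].match_id, points)


class TestDetectStreaks:
    def test_no_streak(self):
        assert detect_streaks([1, 2, 1, 2], 3, 1).tolist() == [0, 0, 0, 0]

    def test_streak_fires_on_third_point(self):
        assert detect_streaks([1, 1, 1], 3, 1).tolist() == [0, 0, 1]

    def test_long_run_fires_repeatedly(self):
        # a 5-point run yields flags on its 3rd, 4th and 5th points
        assert detect_streaks([1] * 5, 3, 1).tolist() == [0, 0, 1, 1, 1]

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            detect_streaks([1, 2], 1, 1)

    def test_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(42)
        victors = rng.integers(1, 3, size=200).tolist()
        for k in (2, 3, 4):
            for player in (1, 2):
                assert detect_streaks(victors, k, player).tolist() == \
                    brute_force_streaks(victors, k, player)

    @given(st.lists(st.sampled_from([1, 2]), max_size=60),
           st.integers(min_value=2, max_value=5),
           st.sampled_from([1, 2]))
    @settings(max_examples=80, deadline=None)
    def test_property_equals_brute_force(self, victors, k, player):
        assert detect_streaks(victors, k, player).tolist() == \
            brute_force_streaks(victors, k, player)


class TestExtractFlags:
    def test_ace_sets_winning_serve_flag(self):
        match = _match([PointRecord("A", server=1, point_victor=1, ace_1=1, ace_2=0)])
        (f1, f2), = extract_flags(match)
        assert (f1.serve_win, f1.shot_win) == (1, 0)
        assert f2.positive() == (0, 0, 0)

    def test_opponent_double_fault_gives_no_positive_flag(self):
        # only a player's active winning play counts as a gain event
        match = _match([PointRecord("A", server=2, point_victor=1, double_fault_2=1)])
        (f1, f2), = extract_flags(match)
        assert f2.double_fault == 1
        assert f1.positive() == (0, 0, 0)

    def test_serve_win_precedence_suppresses_shot_win(self):
        match = _match([PointRecord("A", server=1, point_victor=1, ace_1=1, winner_1=1)])
        (f1, _), = extract_flags(match)
        assert (f1.serve_win, f1.shot_win) == (1, 0)

    def test_p1_definition_ace_only_ignores_serve_winner(self):
        match = _match([PointRecord("A", server=1, point_victor=1, ace_1=0, serve_winner_1=1)])
        (f_both, _), = extract_flags(match, "ace_or_serve_winner")
        (f_ace, _), = extract_flags(match, "ace")
        assert f_both.serve_win == 1
        assert f_ace.serve_win == 0

    def test_streak_flags_from_victor_sequence(self):
        points = [PointRecord("A", server=1, point_victor=1, point_no=i + 1)
                  for i in range(4)]
        flags = extract_flags(_match(points))
        assert [pair[0].streak3_win for pair in flags] == [0, 0, 1, 1]
        assert [pair[1].streak3_loss for pair in flags] == [0, 0, 1, 1]

    def test_streak_flags_mutually_exclusive(self, sim_match):
        match, _ = sim_match
        for f1, f2 in extract_flags(match):
            assert not (f1.streak3_win and f1.streak3_loss)
            assert not (f2.streak3_win and f2.streak3_loss)

    def test_serve_restricted_flags_require_serving(self, sim_corpus):
        for match, _ in sim_corpus[:5]:
            for f1, f2 in extract_flags(match):
                for f in (f1, f2):
                    if f.serve_win or f.double_fault:
                        assert f.serving

    def test_relabeling_players_swaps_streams(self, sim_match):
        match, _ = sim_match
        original = extract_flags(match)
        swapped = extract_flags(swap_players(match))
        assert all(o == (s[1], s[0]) for o, s in zip(original, swapped))

    def test_three_win_three_loss_symmetry(self, sim_corpus):
        # A's three-wins count equals B's three-losses count, per match
        for match, _ in sim_corpus:
            flags = extract_flags(match)
            assert sum(p[0].streak3_win for p in flags) == sum(p[1].streak3_loss for p in flags)
            assert sum(p[1].streak3_win for p in flags) == sum(p[0].streak3_loss for p in flags)

    def test_unknown_definition_rejected(self, sim_match):
        with pytest.raises(ValueError):
            extract_flags(sim_match[0], "serve_only")

    def test_absent_indicators_give_zero_flags_with_warning(self, caplog):
        match = _match([PointRecord("A", server=1, point_victor=1)])
        with caplog.at_level("WARNING"):
            (f1, _), = extract_flags(match)
        assert f1.positive() == (0, 0, 0) and f1.negative() == (0, 0, 0)
        assert any("absent" in rec.message for rec in caplog.records)


class TestDetectBreakPoints:
    def test_30_40_is_break_point_for_receiver(self):
        victors = [2, 2, 1, 1, 2]  # game score 30-40, server 1
        points = [PointRecord("A", server=1, point_victor=v, point_no=i + 1)
                  for i, v in enumerate(victors)] + \
                 [PointRecord("A", server=1, point_victor=2, point_no=6, game_victor=2)]
        ctx = detect_break_points(_match(points))
        assert ctx[5].is_break_point and ctx[5].receiver == 2
        assert ctx[5].converted

    def test_advantage_receiver_is_break_point(self):
        victors = [1, 2, 1, 2, 1, 2, 2]  # deuce then advantage receiver
        points = [PointRecord("A", server=1, point_victor=v, point_no=i + 1)
                  for i, v in enumerate(victors)]
        points.append(PointRecord("A", server=1, point_victor=1, point_no=8))
        ctx = detect_break_points(_match(points))
        assert ctx[7].is_break_point
        assert not ctx[7].converted

    def test_deuce_is_not_break_point(self):
        victors = [1, 2, 1, 2, 1, 2]
        points = [PointRecord("A", server=1, point_victor=v, point_no=i + 1)
                  for i, v in enumerate(victors)]
        points.append(PointRecord("A", server=1, point_victor=2, point_no=7))
        ctx = detect_break_points(_match(points))
        assert not ctx[6].is_break_point

    def test_reconstruction_matches_simulator_truth(self, sim_corpus):
        for match, truth in sim_corpus[:8]:
            stripped = strip_break_point_columns(match)
            ctx = detect_break_points(stripped)
            for c, (tf1, tf2) in zip(ctx, truth.flags):
                truth_bp = tf1.is_break_point or tf2.is_break_point
                truth_conv = tf1.break_point_converted or tf2.break_point_converted
                assert c.is_break_point == truth_bp
                assert c.converted == truth_conv

    def test_provided_columns_take_precedence(self):
        point = PointRecord("A", server=1, point_victor=2, break_pt_2=1, break_pt_won_2=1)
        ctx = detect_break_points(_match([point]))
        assert ctx[0].is_break_point and ctx[0].converted


class TestTallyEvents:
    def test_no_events_all_zero(self):
        points = [PointRecord("A", server=1, point_victor=1, point_no=1,
                              ace_1=0, winner_1=0, double_fault_1=0, unf_err_1=0),
                  PointRecord("A", server=2, point_victor=2, point_no=2,
                              ace_2=0, winner_2=0, double_fault_2=0, unf_err_2=0)]
        match = _match(points)
        t1, t2 = tally_events(match, extract_flags(match))
        assert t1.n_winning_shots == t2.n_winning_shots == 0
        assert t1.rate_winning_serve == 0.0

    def test_hand_built_ten_point_match(self):
        # player 1 serves all 10 points: 2 rally winners, 1 double fault
        points = []
        victors = [1, 1, 2, 1, 2, 1, 1, 2, 1, 1]
        for i, v in enumerate(victors):
            points.append(PointRecord("A", server=1, point_victor=v, point_no=i + 1))
        points[0].winner_1 = 1
        points[3].winner_1 = 1
        points[2].double_fault_1 = 1
        match = _match(points)
        t1, _ = tally_events(match, extract_flags(match))
        assert t1.n_winning_shots == 2
        assert t1.rate_double_fault == pytest.approx(1 / 10)
        assert t1.rate_winning_serve == 0.0

    def test_zero_service_points_rate_absent(self):
        points = [PointRecord("A", server=2, point_victor=1, point_no=1)]
        match = _match(points)
        t1, _ = tally_events(match, extract_flags(match))
        assert t1.rate_winning_serve is None
        assert t1.rate_double_fault is None

    def test_tallies_match_simulator_bookkeeping(self, sim_corpus):
        total_points = 0
        for match, truth in sim_corpus:
            total_points += len(match.points)
            flags = extract_flags(match)
            tallies = tally_events(match, flags)
            for player, tally in zip((1, 2), tallies):
                c = truth.counts[player]
                assert tally.n_winning_shots == c["winners"]
                assert tally.n_unforced_errors == c["unf_errs"]
                assert tally.n_three_consecutive_wins == c["streak3_wins"]
                assert tally.n_three_consecutive_losses == c["streak3_losses"]
                assert tally.n_net_points == c["net_pts"]
                assert tally.n_net_points_won == c["net_pts_won"]
        assert total_points > 1000  # corpus-scale check, not a toy


def test_flags_frame_has_twelve_streams(sim_match):
    match, _ = sim_match
    frame = flags_to_frame(extract_flags(match))
    assert frame.shape == (len(match.points), 12)
    assert set(frame.to_numpy().ravel()) <= {0, 1}
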