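"""Per-point momentum-event flags and match-level event tallies.

Six events drive the momentum model, three positive (winning serve,
winning shot, three consecutive points won) and three negative (double
fault, unforced error, three consecutive points lost).  Only a player's
own active play raises a flag: an opponent's unforced error is never
credited as a winning shot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from matchmomentum.match_io import MatchRecord

logger = logging.getLogger("matchmomentum.events")

#: Positive / negative flag names, in weight order.
POSITIVE_FLAGS = ("serve_win", "shot_win", "streak3_win")
NEGATIVE_FLAGS = ("double_fault", "unforced_error", "streak3_loss")
FLAG_NAMES = POSITIVE_FLAGS + NEGATIVE_FLAGS


@dataclass
class EventFlags:
    """One player's event flags and context at one point."""

    serve_win: int = 0
    shot_win: int = 0
    streak3_win: int = 0
    double_fault: int = 0
    unforced_error: int = 0
    streak3_loss: int = 0
    serving: bool = False
    is_break_point: bool = False
    break_point_converted: bool = False

    def positive(self) -> tuple[int, int, int]:
        return (self.serve_win, self.shot_win, self.streak3_win)

    def negative(self) -> tuple[int, int, int]:
        return (self.double_fault, self.unforced_error, self.streak3_loss)


@dataclass
class EventTally:
    """Match-level event totals for one player (winner/loser table shape)."""

    rate_winning_serve: float | None = None
    n_winning_shots: int = 0
    n_three_consecutive_wins: int = 0
    rate_double_fault: float | None = None
    n_unforced_errors: int = 0
    n_three_consecutive_losses: int = 0
    n_net_points: int = 0
    n_net_points_won: int = 0
    total_distance_run: float = 0.0


@dataclass(frozen=True)
class BreakPointContext:
    """Break-point status of one point, seen from the receiver's side."""

    receiver: int
    is_break_point: bool
    converted: bool


def detect_streaks(victors: Sequence[int], k: int, player: int) -> np.ndarray:
    """Flag every point that completes a run of ``k`` wins for ``player``.

    ``out[i] = 1`` iff the player won points ``i-k+1 .. i`` inclusive, so a
    run of length 5 with k=3 fires on its 3rd, 4th and 5th points.
    """
    if k < 2:
        raise ValueError(f"streak length k must be >= 2, got {k}")
    won = np.asarray([1 if v == player else 0 for v in victors], dtype=np.int64)
    out = np.zeros_like(won)
    if len(won) >= k:
        window = np.convolve(won, np.ones(k, dtype=np.int64), mode="valid")
        out[k - 1:] = (window == k).astype(np.int64)
    return out


def detect_break_points(match: MatchRecord) -> list[BreakPointContext]:
    """Per-point break-point context for the receiver.

    When the source provides break_pt columns they are trusted; otherwise
    the game score is reconstructed from the victor sequence.  A point is a
    break point iff the receiver wins the game by winning it (receiver at
    3+ points with at least a one-point lead, win-by-two scoring).
    Tiebreak points are never break points.
    """
    out: list[BreakPointContext] = []
    game_key = None
    pts = {1: 0, 2: 0}
    games_in_set = {1: 0, 2: 0}
    current_set = None

    for point in match.points:
        if point.set_no != current_set:
            current_set = point.set_no
            games_in_set = {1: 0, 2: 0}
        if (point.set_no, point.game_no) != game_key:
            game_key = (point.set_no, point.game_no)
            pts = {1: 0, 2: 0}

        receiver = point.receiver
        tiebreak = games_in_set[1] >= 6 and games_in_set[2] >= 6

        raw = point.indicator("break_pt", receiver)
        if raw is not None:
            is_bp = bool(raw)
            raw_won = point.indicator("break_pt_won", receiver)
            converted = bool(raw_won) if raw_won is not None else (is_bp and point.point_victor == receiver)
        else:
            is_bp = (not tiebreak
                     and pts[receiver] >= 3
                     and pts[receiver] - pts[point.server] >= 1)
            converted = is_bp and point.point_victor == receiver
        out.append(BreakPointContext(receiver, is_bp, converted))

        pts[point.point_victor] += 1
        if point.game_victor in (1, 2):
            games_in_set[point.game_victor] += 1
    return out


def extract_flags(
    match: MatchRecord,
    p1_definition: str = "ace_or_serve_winner",
) -> list[tuple[EventFlags, EventFlags]]:
    """Derive both players' event flags for every point of a match.

    ``p1_definition`` controls what counts as a winning serve: ``"ace"``
    (aces only) or ``"ace_or_serve_winner"`` (aces plus untouched serve
    winners).  If a point is both a winning serve and a generic winner the
    serve flag takes precedence, so one point contributes one gain event.
    Absent raw indicator columns yield 0 flags with a warning.
    """
    if p1_definition not in ("ace", "ace_or_serve_winner"):
        raise ValueError(f"unknown p1_definition {p1_definition!r}")

    victors = [p.point_victor for p in match.points]
    streaks = {x: detect_streaks(victors, 3, x) for x in (1, 2)}
    bp_context = detect_break_points(match)

    missing_stems: set[str] = set()
    result: list[tuple[EventFlags, EventFlags]] = []
    for i, point in enumerate(match.points):
        pair = []
        for player in (1, 2):
            serving = point.server == player
            won = point.point_victor == player

            def flag(stem: str) -> int:
                value = point.indicator(stem, player)
                if value is None:
                    missing_stems.add(stem)
                    return 0
                return int(value)

            serve_win = 0
            if serving and won:
                serve_win = flag("ace")
                if not serve_win and p1_definition == "ace_or_serve_winner":
                    serve_win = flag("serve_winner")
            shot_win = 0
            if won and not serve_win:
                shot_win = flag("winner")
            double_fault = flag("double_fault") if serving and not won else 0
            unforced = flag("unf_err") if not won else 0

            context = bp_context[i]
            is_bp = context.is_break_point and context.receiver == player
            pair.append(EventFlags(
                serve_win=serve_win,
                shot_win=shot_win,
                streak3_win=int(streaks[player][i]),
                double_fault=double_fault,
                unforced_error=unforced,
                streak3_loss=int(streaks[2 if player == 1 else 1][i]),
                serving=serving,
                is_break_point=is_bp,
                break_point_converted=is_bp and context.converted,
            ))
        result.append((pair[0], pair[1]))

    if missing_stems:
        logger.warning("match %s: indicator column(s) absent, flags default to 0: %s",
                       match.match_id, ", ".join(sorted(missing_stems)))
    return result


def tally_events(
    match: MatchRecord,
    flags: Sequence[tuple[EventFlags, EventFlags]],
) -> tuple[EventTally, EventTally]:
    """Sum per-point flags into winner/loser-table event totals.

    Serve rates are per service point of the player; with zero service
    points the rate is ``None`` (absent).
    """
    tallies = []
    for idx, player in enumerate((1, 2)):
        stream = [pair[idx] for pair in flags]
        service_points = sum(1 for p in match.points if p.server == player)
        serve_wins = sum(f.serve_win for f in stream)
        double_faults = sum(f.double_fault for f in stream)
        tally = EventTally(
            rate_winning_serve=serve_wins / service_points if service_points else None,
            n_winning_shots=sum(f.shot_win for f in stream),
            n_three_consecutive_wins=sum(f.streak3_win for f in stream),
            rate_double_fault=double_faults / service_points if service_points else None,
            n_unforced_errors=sum(f.unforced_error for f in stream),
            n_three_consecutive_losses=sum(f.streak3_loss for f in stream),
            n_net_points=sum((p.indicator("net_pt", player) or 0) for p in match.points),
            n_net_points_won=sum((p.indicator("net_pt_won", player) or 0) for p in match.points),
            total_distance_run=sum((getattr(p, f"distance_run_{player}") or 0.0)
                                   for p in match.points),
        )
        tallies.append(tally)
    return tallies[0], tallies[1]


def flags_to_frame(flags: Sequence[tuple[EventFlags, EventFlags]]) -> pd.DataFrame:
    """The twelve flag streams as a DataFrame (columns ``<flag>_<player>``)."""
    data = {}
    for idx, player in enumerate((1, 2)):
        for name in FLAG_NAMES:
            data[f"{name}_{player}"] = [getattr(pair[idx], name) for pair in flags]
    return pd.DataFrame(data)
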