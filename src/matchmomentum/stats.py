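"""Event-level statistics: contingency tests, court summaries, correlations.

These reproduce the analysis layer around the momentum model: the
server-vs-game-winner association, winner/loser event tallies, min-max
normalised indicator variance across court types, Pearson correlation of
the twelve event-flag streams, and cumulative score time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from matchmomentum.events import FLAG_NAMES, detect_streaks, flags_to_frame
from matchmomentum.match_io import MatchRecord

logger = logging.getLogger("matchmomentum.stats")

#: Smallest reportable p-value; an exact-zero survival value is floored here.
P_VALUE_FLOOR = 1e-300


@dataclass
class ContingencyTable:
    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float


class InvalidTestError(ValueError):
    """The table cannot support a chi-square test (zero marginal)."""


def chi_square(table: ContingencyTable, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    Expected counts come from the marginals; the p-value is the upper tail
    at ``(r-1)(c-1)`` degrees of freedom.  No continuity correction by
    default.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise InvalidTestError("zero marginal: chi-square test undefined")
    stat, p, dof, _ = chi2_contingency(counts, correction=correction)
    p = float(p)
    if p == 0.0:
        p = P_VALUE_FLOOR
    return ChiSquareResult(statistic=float(stat), dof=int(dof), p_value=p)


def server_outcome_table(corpus: Sequence[MatchRecord]) -> tuple[ContingencyTable, float]:
    """Cross-tabulate server identity against game winner over a corpus.

    Only game-concluding points count.  Also returns the server game-win
    rate P(game winner = server).
    """
    counts = np.zeros((2, 2), dtype=np.int64)
    for match in corpus:
        for point in match.points:
            if point.game_victor in (1, 2):
                counts[point.server - 1, point.game_victor - 1] += 1
    total = int(counts.sum())
    if total == 0:
        raise ValueError("corpus contains no completed games")
    rate = float((counts[0, 0] + counts[1, 1]) / total)
    table = ContingencyTable(["server=1", "server=2"], ["game_winner=1", "game_winner=2"], counts)
    return table, rate


#: Indicators summarised per court type (per-point corpus means / rates).
COURT_INDICATORS = (
    "distance_run", "serve_speed", "rally_count", "double_fault",
    "unforced_error", "ace", "winning_shot", "three_consecutive_wins",
    "three_consecutive_losses",
)


def _corpus_indicators(corpus: Sequence[MatchRecord]) -> dict[str, tuple]:
    """Per-point (sum, count, min, max) of the court-sensitive indicators."""
    sums = {name: 0.0 for name in COURT_INDICATORS}
    counts = {name: 0 for name in COURT_INDICATORS}
    lows = {name: np.inf for name in COURT_INDICATORS}
    highs = {name: -np.inf for name in COURT_INDICATORS}

    def add(name: str, value) -> None:
        if value is not None:
            value = float(value)
            sums[name] += value
            counts[name] += 1
            lows[name] = min(lows[name], value)
            highs[name] = max(highs[name], value)

    for match in corpus:
        victors = [p.point_victor for p in match.points]
        streak = {x: detect_streaks(victors, 3, x) for x in (1, 2)}
        for i, point in enumerate(match.points):
            add("rally_count", point.rally_count)
            add("serve_speed", point.serve_speed)
            for x in (1, 2):
                add("distance_run", getattr(point, f"distance_run_{x}"))
                add("double_fault", point.indicator("double_fault", x))
                add("unforced_error", point.indicator("unf_err", x))
                add("ace", point.indicator("ace", x))
                add("winning_shot", point.indicator("winner", x))
                add("three_consecutive_wins", int(streak[x][i]))
                add("three_consecutive_losses", int(streak[2 if x == 1 else 1][i]))
    return {name: ((sums[name] / counts[name], lows[name], highs[name])
                   if counts[name] else None)
            for name in COURT_INDICATORS}


def court_type_summary(corpora: dict[str, Sequence[MatchRecord]]) -> pd.DataFrame:
    """Min-max-normalised indicator values and their variance across courts.

    Per indicator, the point-level observations pooled over all court
    types set the [0, 1] min-max scale; each court's mean is normalised on
    that scale and the population variance of the normalised means is
    taken.  (Normalising the per-court aggregates themselves would pin the
    extremes to 0 and 1 and erase effect size.)  Indicators missing for
    any court type are excluded with a warning.
    """
    if len(corpora) < 2:
        raise ValueError("need at least two court types")
    per_court = {court: _corpus_indicators(corpus) for court, corpus in corpora.items()}
    courts = list(per_court)

    rows = {}
    for name in COURT_INDICATORS:
        values = [per_court[c][name] for c in courts]
        if any(v is None for v in values):
            logger.warning("indicator %s missing for some court type(s); excluded", name)
            continue
        means = np.asarray([v[0] for v in values])
        low = min(v[1] for v in values)
        high = max(v[2] for v in values)
        span = high - low
        normalized = (means - low) / span if span > 0 else np.zeros_like(means)
        rows[name] = list(normalized) + [float(np.var(normalized))]
    return pd.DataFrame.from_dict(rows, orient="index", columns=courts + ["variance"])


def event_correlation(flags_corpus: Sequence) -> pd.DataFrame:
    """Pearson (phi) correlation matrix over the twelve event-flag streams.

    ``flags_corpus`` is one or more per-match flag sequences (as produced
    by ``extract_flags``); streams are concatenated across matches.
    Zero-variance streams yield NaN entries (reported as absent).
    """
    frames = [flags_to_frame(flags) for flags in flags_corpus]
    frame = pd.concat(frames, ignore_index=True)
    if len(frame) < 2:
        raise ValueError("need at least two points for a correlation matrix")
    return frame.corr(method="pearson")


def event_tally_frame(tallies: Sequence[tuple]) -> pd.DataFrame:
    """Stack per-match (player 1, player 2) tallies into a corpus table."""
    rows = []
    for i, (t1, t2) in enumerate(tallies, start=1):
        for player, tally in ((1, t1), (2, t2)):
            row = {"match_index": i, "player": player}
            row.update(vars(tally))
            rows.append(row)
    return pd.DataFrame(rows)


def score_time_series(match: MatchRecord) -> pd.DataFrame:
    """Cumulative points, games and sets per player over the point index."""
    n = len(match.points)
    data = {f"{kind}_{x}": np.zeros(n, dtype=np.int64)
            for kind in ("points", "games", "sets") for x in (1, 2)}
    totals = {f"{kind}_{x}": 0 for kind in ("points", "games", "sets") for x in (1, 2)}
    for i, point in enumerate(match.points):
        totals[f"points_{point.point_victor}"] += 1
        if point.game_victor in (1, 2):
            totals[f"games_{point.game_victor}"] += 1
        if point.set_victor in (1, 2):
            totals[f"sets_{point.set_victor}"] += 1
        for key in data:
            data[key][i] = totals[key]
    frame = pd.DataFrame(data)
    frame.insert(0, "point_no", [p.point_no for p in match.points])
    return frame


__all__ = [
    "ContingencyTable", "ChiSquareResult", "InvalidTestError", "chi_square",
    "server_outcome_table", "court_type_summary", "event_correlation",
    "event_tally_frame", "score_time_series", "COURT_INDICATORS", "FLAG_NAMES",
]
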