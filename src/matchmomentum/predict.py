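"""Match-winner prediction from the momentum differential.

A match-level score is reduced from each player's momentum series
("final" point value, match "mean", or "cumulative" sum) plus the
break-point set adjustments; the predicted winner is the player with the
higher score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from matchmomentum.events import EventFlags, extract_flags
from matchmomentum.match_io import MatchRecord
from matchmomentum.momentum import (
    MomentumParams,
    MomentumSeries,
    momentum_series,
    set_scores,
)

logger = logging.getLogger("matchmomentum.predict")


@dataclass
class PredictionResult:
    match_id: str
    predicted_winner: int
    momentum_differential: float
    actual_winner: int | None = None
    correct: bool | None = None
    set_score_table: dict[int, tuple[float, float]] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    accuracy: float
    results: list[PredictionResult]
    n_skipped: int = 0

    @property
    def n_matches(self) -> int:
        return len(self.results)


def actual_winner(match: MatchRecord) -> int | None:
    """Match winner from metadata if provided, else from set-victor counts."""
    meta = match.metadata.get("winner")
    if meta in (1, 2):
        return int(meta)
    sets = {1: 0, 2: 0}
    for point in match.points:
        if point.set_victor in (1, 2):
            sets[point.set_victor] += 1
    if sets[1] == sets[2]:
        return None
    return 1 if sets[1] > sets[2] else 2


def match_score(
    series: MomentumSeries,
    flags_stream: Sequence[EventFlags],
    params: MomentumParams,
    mode: str | None = None,
) -> float:
    """One player's match-level score under a prediction mode."""
    mode = mode or params.prediction_mode
    if len(series) == 0:
        raise ValueError("empty momentum series")
    base = {"final": series.final, "mean": series.mean, "cumulative": series.cumulative}[mode]
    created = sum(f.is_break_point for f in flags_stream)
    converted = sum(f.break_point_converted for f in flags_stream)
    return base + params.w_bp_created * created + params.w_bp_converted * converted


def predict_winner(
    match: MatchRecord,
    flags: Sequence[tuple[EventFlags, EventFlags]],
    series: tuple[MomentumSeries, MomentumSeries],
    params: MomentumParams | None = None,
    mode: str | None = None,
) -> PredictionResult:
    """Predict the winner of one match from its momentum series pair.

    Ties in the score break to the player with more total points won, then
    to player 1 (deterministic).
    """
    params = params or MomentumParams.default()
    if len(series[0]) == 0 or len(series[1]) == 0:
        raise ValueError("cannot predict from empty momentum series")
    scores = [match_score(series[idx], [pair[idx] for pair in flags], params, mode)
              for idx in (0, 1)]
    differential = scores[0] - scores[1]
    if scores[0] > scores[1]:
        predicted = 1
    elif scores[1] > scores[0]:
        predicted = 2
    else:
        points_won = {x: sum(1 for p in match.points if p.point_victor == x) for x in (1, 2)}
        predicted = 2 if points_won[2] > points_won[1] else 1

    actual = actual_winner(match)
    return PredictionResult(
        match_id=match.match_id,
        predicted_winner=predicted,
        momentum_differential=differential,
        actual_winner=actual,
        correct=None if actual is None else predicted == actual,
        set_score_table=set_scores(series, match, flags, params),
    )


def predict_match(
    match: MatchRecord,
    params: MomentumParams | None = None,
    mode: str | None = None,
) -> PredictionResult:
    """Full pipeline for one match: flags -> momentum -> prediction."""
    params = params or MomentumParams.default()
    flags = extract_flags(match, params.p1_definition)
    series = momentum_series(match, flags, params)
    return predict_winner(match, flags, series, params, mode)


def evaluate_corpus(
    corpus: Sequence[MatchRecord],
    params: MomentumParams | None = None,
    mode: str | None = None,
) -> EvaluationReport:
    """Prediction accuracy over a corpus of completed matches.

    Matches without a derivable actual winner are skipped with a warning
    and reported in ``n_skipped``.  Results are sorted by match_id.
    """
    params = params or MomentumParams.default()
    results = []
    skipped = 0
    for match in corpus:
        if actual_winner(match) is None:
            logger.warning("match %s: actual winner undecidable; skipped", match.match_id)
            skipped += 1
            continue
        results.append(predict_match(match, params, mode))
    if not results:
        raise ValueError("no evaluable matches in corpus")
    results.sort(key=lambda r: r.match_id)
    accuracy = sum(r.correct for r in results) / len(results)
    return EvaluationReport(accuracy=accuracy, results=results, n_skipped=skipped)


def evaluate_modes(
    corpus: Sequence[MatchRecord],
    params: MomentumParams | None = None,
) -> dict[str, float]:
    """Accuracy of every prediction mode on the same corpus."""
    from matchmomentum.momentum import PREDICTION_MODES

    return {mode: evaluate_corpus(corpus, params, mode).accuracy
            for mode in PREDICTION_MODES}
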