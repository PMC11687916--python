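"""The momentum difference equation with exponential forgetting.

Per player, momentum evolves as ``M_i = f(dt_i) * M_{i-1} + dM_i`` with
``M_0 = 0``.  The forgetting coefficient ``f(dt) = floor + scale *
exp(-lambda * dt)`` decays from 1 at dt=0 towards the floor, so older
momentum is progressively discounted over long pauses.  The increment is
a linear weighting of the six event flags, scaled up for positive events
on serve and for negative events on return.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from matchmomentum.events import EventFlags
from matchmomentum.match_io import MatchRecord

#: Memory half-life fallback: the transient component halves over a typical
#: 40 s inter-point gap.  The decay rate is a free model constant.
DEFAULT_LAMBDA = math.log(2) / 40.0

PREDICTION_MODES = ("final", "mean", "cumulative")


@dataclass
class MomentumParams:
    """All model constants; shipped defaults live in ``data/defaults.yaml``."""

    lambda_decay: float = DEFAULT_LAMBDA
    f_floor: float = 0.6
    f_scale: float = 0.4
    alpha_serve: float = 1.2
    alpha_recv: float = 1.0
    beta_serve: float = 1.0
    beta_recv: float = 1.2
    w_p: tuple[float, float, float] = (0.30, 0.32, 0.38)
    w_n: tuple[float, float, float] = (0.32, 0.26, 0.42)
    w_bp_created: float = 0.05
    w_bp_converted: float = 0.10
    default_dt_seconds: float = 40.0
    prediction_mode: str = "mean"
    p1_definition: str = "ace_or_serve_winner"

    def __post_init__(self) -> None:
        self.w_p = tuple(self.w_p)
        self.w_n = tuple(self.w_n)
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be > 0")
        if not math.isclose(self.f_floor + self.f_scale, 1.0, abs_tol=1e-12):
            raise ValueError("f_floor + f_scale must equal 1 so that f(0) = 1")
        if len(self.w_p) != 3 or len(self.w_n) != 3:
            raise ValueError("w_p and w_n must each have three weights")
        for w in (*self.w_p, *self.w_n, self.w_bp_created, self.w_bp_converted,
                  self.alpha_serve, self.alpha_recv, self.beta_serve, self.beta_recv):
            if w < 0:
                raise ValueError("weights must be nonnegative")
        if not math.isclose(sum(self.w_p), 1.0, abs_tol=1e-9):
            raise ValueError("positive event weights must sum to 1")
        if not math.isclose(sum(self.w_n), 1.0, abs_tol=1e-9):
            raise ValueError("negative event weights must sum to 1")
        if self.default_dt_seconds <= 0:
            raise ValueError("default_dt_seconds must be > 0")
        if self.prediction_mode not in PREDICTION_MODES:
            raise ValueError(f"prediction_mode must be one of {PREDICTION_MODES}")

    @classmethod
    def from_dict(cls, data: dict) -> "MomentumParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def default(cls) -> "MomentumParams":
        """The shipped defaults, loaded from the packaged YAML file."""
        text = resources.files("matchmomentum").joinpath("data/defaults.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text)["momentum"])

    def with_overrides(self, **overrides) -> "MomentumParams":
        return replace(self, **overrides)


@dataclass
class MomentumSeries:
    """One player's momentum trajectory aligned to the point sequence."""

    m: np.ndarray
    delta: np.ndarray
    f: np.ndarray

    def __len__(self) -> int:
        return len(self.m)

    @property
    def final(self) -> float:
        return float(self.m[-1])

    @property
    def mean(self) -> float:
        return float(np.mean(self.m))

    @property
    def cumulative(self) -> float:
        return float(np.sum(self.m))


def forgetting_coefficient(dt_seconds: float, params: MomentumParams) -> float:
    """Memory retention after a gap of ``dt_seconds``; 1 at dt=0, floor at infinity."""
    if dt_seconds < 0:
        raise ValueError(f"dt_seconds must be >= 0, got {dt_seconds}")
    return params.f_floor + params.f_scale * math.exp(-params.lambda_decay * dt_seconds)


def momentum_increment(flags: EventFlags, params: MomentumParams) -> float:
    """Event-driven momentum change for one player at one point.

    Positive events add ``alpha * w_p``, negative events subtract
    ``beta * w_n``; alpha favours the server (1.2 vs 1), beta penalises
    the receiver's negative events more (1.2 vs 1).
    """
    alpha = params.alpha_serve if flags.serving else params.alpha_recv
    beta = params.beta_serve if flags.serving else params.beta_recv
    gain = sum(w * flag for w, flag in zip(params.w_p, flags.positive()))
    loss = sum(w * flag for w, flag in zip(params.w_n, flags.negative()))
    return alpha * gain - beta * loss


def max_abs_increment(params: MomentumParams) -> float:
    """Reachable bound on |dM| given flag exclusivity.

    Winning-serve and winning-shot flags are mutually exclusive, and a
    player cannot carry positive and negative flags on the same point
    (positives require winning it, negatives losing it).
    """
    pos = max(params.alpha_serve, params.alpha_recv) * (
        max(params.w_p[0], params.w_p[1]) + params.w_p[2])
    neg = max(params.beta_serve, params.beta_recv) * sum(params.w_n)
    return max(pos, neg)


def point_gaps(match: MatchRecord, params: MomentumParams) -> np.ndarray:
    """Inter-point gaps (seconds) from the cumulative clock.

    Missing or non-positive differences fall back to the default gap; the
    first point always uses the default (its forgetting factor multiplies
    ``M_0 = 0`` and is therefore inert).
    """
    elapsed = [p.elapsed_seconds for p in match.points]
    gaps = np.full(len(elapsed), params.default_dt_seconds, dtype=float)
    for i in range(1, len(elapsed)):
        if elapsed[i] is not None and elapsed[i - 1] is not None:
            dt = elapsed[i] - elapsed[i - 1]
            if dt > 0:
                gaps[i] = dt
    return gaps


def momentum_series(
    match: MatchRecord,
    flags: Sequence[tuple[EventFlags, EventFlags]],
    params: MomentumParams | None = None,
) -> tuple[MomentumSeries, MomentumSeries]:
    """Run the recursion for both players over one match.

    Each player's series depends only on their own flags; the opponent
    enters through the shared victor sequence (streak flags).
    """
    params = params or MomentumParams.default()
    n = len(match.points)
    if len(flags) != n:
        raise ValueError(f"flags length {len(flags)} != number of points {n}")

    gaps = point_gaps(match, params)
    bound = max_abs_increment(params)
    out = []
    for idx in (0, 1):
        f = np.array([forgetting_coefficient(dt, params) for dt in gaps])
        delta = np.array([momentum_increment(pair[idx], params) for pair in flags])
        assert np.all(np.abs(delta) <= bound + 1e-12), "increment exceeded reachable bound"
        m = np.empty(n)
        prev = 0.0
        for i in range(n):
            prev = f[i] * prev + delta[i]
            m[i] = prev
        out.append(MomentumSeries(m=m, delta=delta, f=f))
    return out[0], out[1]


def set_scores(
    series: tuple[MomentumSeries, MomentumSeries],
    match: MatchRecord,
    flags: Sequence[tuple[EventFlags, EventFlags]],
    params: MomentumParams | None = None,
) -> dict[int, tuple[float, float]]:
    """Per-set scores: mean momentum plus the break-point adjustment.

    ``S = mean(M over the set) + w_bp_created * (break points created)
    + w_bp_converted * (break points converted)``, per player.  The
    adjustment rewards pressure built on the opponent's serve; with zero
    weights the scores reduce to plain set means.
    """
    params = params or MomentumParams.default()
    set_nos = np.array([p.set_no for p in match.points])
    scores: dict[int, tuple[float, float]] = {}
    for s in sorted(set(set_nos.tolist())):
        mask = set_nos == s
        per_player = []
        for idx in (0, 1):
            base = float(np.mean(series[idx].m[mask]))
            created = sum(pair[idx].is_break_point for pair, inside in zip(flags, mask) if inside)
            converted = sum(pair[idx].break_point_converted for pair, inside in zip(flags, mask) if inside)
            per_player.append(base
                              + params.w_bp_created * created
                              + params.w_bp_converted * converted)
        scores[int(s)] = (per_player[0], per_player[1])
    return scores
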