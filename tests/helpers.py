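"""Independent oracles and small utilities shared across the test suite.

Oracles here deliberately avoid the package's computation paths: streaks
by literal window scan, chi-square from the textbook expected-count
formula, momentum from the unrolled product-sum form.
"""

from __future__ import annotations

import copy
import math

import numpy as np
from scipy.stats import chi2

from matchmomentum.match_io import INDICATOR_STEMS, MatchRecord


def brute_force_streaks(victors, k, player):
    """Literal sliding-window streak scan."""
    out = []
    for i in range(len(victors)):
        if i >= k - 1 and all(v == player for v in victors[i - k + 1: i + 1]):
            out.append(1)
        else:
            out.append(0)
    return out


def chi_square_oracle(counts):
    """Textbook Pearson statistic from the brute-force expected matrix."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    stat = float(((counts - expected) ** 2 / expected).sum())
    dof = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, dof, float(chi2.sf(stat, dof))


def unrolled_momentum(flags_stream, gaps, params):
    """Unrolled form M_n = sum_i (prod_{j>i} f_j) * dM_i, written from scratch."""
    n = len(flags_stream)
    f = np.array([params.f_floor + params.f_scale * math.exp(-params.lambda_decay * dt)
                  for dt in gaps])
    delta = np.empty(n)
    for i, fl in enumerate(flags_stream):
        alpha = params.alpha_serve if fl.serving else params.alpha_recv
        beta = params.beta_serve if fl.serving else params.beta_recv
        delta[i] = alpha * (params.w_p[0] * fl.serve_win
                            + params.w_p[1] * fl.shot_win
                            + params.w_p[2] * fl.streak3_win) \
            - beta * (params.w_n[0] * fl.double_fault
                      + params.w_n[1] * fl.unforced_error
                      + params.w_n[2] * fl.streak3_loss)
    prods = np.cumprod(f)
    weighted = np.cumsum(delta / prods)
    return prods * weighted


def random_flag_stream(rng, n):
    """Random event-flag stream respecting exclusivity (win xor loss events)."""
    from matchmomentum.events import EventFlags

    stream = []
    for _ in range(n):
        serving = bool(rng.integers(0, 2))
        won = bool(rng.integers(0, 2))
        flags = EventFlags(serving=serving)
        if won:
            if rng.random() < 0.4:
                if serving and rng.random() < 0.5:
                    flags.serve_win = 1
                else:
                    flags.shot_win = 1
            flags.streak3_win = int(rng.random() < 0.25)
        else:
            if serving and rng.random() < 0.15:
                flags.double_fault = 1
            elif rng.random() < 0.3:
                flags.unforced_error = 1
            flags.streak3_loss = int(rng.random() < 0.25)
        stream.append(flags)
    return stream


def match_with_gaps(rng, n, match_id="R"):
    """Bare match skeleton with a random cumulative clock."""
    from matchmomentum.match_io import PointRecord

    elapsed = np.cumsum(rng.uniform(5.0, 120.0, size=n))
    points = [PointRecord(match_id, point_no=i + 1, server=1 + i % 2,
                          point_victor=int(rng.integers(1, 3)),
                          elapsed_seconds=float(elapsed[i]))
              for i in range(n)]
    return MatchRecord(match_id, points)


def swap_players(match: MatchRecord) -> MatchRecord:
    """Relabel players 1 <-> 2 in every point (and match metadata)."""
    flipped = copy.deepcopy(match)

    def flip(v):
        return {1: 2, 2: 1}.get(v, v)

    for point in flipped.points:
        point.server = flip(point.server)
        point.point_victor = flip(point.point_victor)
        point.game_victor = flip(point.game_victor)
        point.set_victor = flip(point.set_victor)
        for stem in (*INDICATOR_STEMS, "distance_run"):
            a = getattr(point, f"{stem}_1")
            b = getattr(point, f"{stem}_2")
            setattr(point, f"{stem}_1", b)
            setattr(point, f"{stem}_2", a)
    if "winner" in flipped.metadata:
        flipped.metadata["winner"] = flip(flipped.metadata["winner"])
    return flipped


def strip_break_point_columns(match: MatchRecord) -> MatchRecord:
    """Remove raw break-point annotations so reconstruction must kick in."""
    stripped = copy.deepcopy(match)
    for point in stripped.points:
        point.break_pt_1 = point.break_pt_2 = None
        point.break_pt_won_1 = point.break_pt_won_2 = None
    return stripped
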