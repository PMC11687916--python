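"""Synthetic point-by-point match generation.

A full tennis scoring state machine (game / deuce / set / tiebreak /
match, standard rules) driven by a seeded stochastic event model.  Every
simulated match is schema-valid and ships with ground-truth annotations
(event flags, break points, inter-point gaps) so the extraction, momentum
and prediction stages can be tested end-to-end against a generator-side
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from matchmomentum.events import EventFlags
from matchmomentum.match_io import MatchRecord, PointRecord

#: Court-specific shifts: serve speed (km/h), mean rally length, ace-rate
#: multiplier.  Only speed, rally and aces vary with the surface; fault and
#: error rates are court-invariant.
COURT_EFFECTS = {
    "hard": {"serve_speed_mean": 195.0, "rally_mean": 4.0, "ace_multiplier": 1.0},
    "grass": {"serve_speed_mean": 180.0, "rally_mean": 3.5, "ace_multiplier": 1.2},
    "clay": {"serve_speed_mean": 172.0, "rally_mean": 5.5, "ace_multiplier": 0.5},
}


def _other(player: int) -> int:
    return 2 if player == 1 else 1


@dataclass
class ScoringState:
    """Mutable score state of a match in progress (standard rules).

    Games go to 4 points win-by-2 with deuce; sets to 6 games win-by-2
    with a 7-point tiebreak at 6-6 (configurable for the final set); the
    match goes to the best-of majority of sets.  The server alternates by
    game; tiebreak serving follows the 1-2-2-... pattern and the tiebreak
    counts as one service game for the rotation.
    """

    best_of: int = 3
    final_set_tiebreak: bool = True
    server: int = 1
    points: dict = field(default_factory=lambda: {1: 0, 2: 0})
    games: dict = field(default_factory=lambda: {1: 0, 2: 0})
    sets: dict = field(default_factory=lambda: {1: 0, 2: 0})
    in_tiebreak: bool = False
    tb_first_server: int = 0
    finished: bool = False
    winner: int = 0

    @property
    def set_no(self) -> int:
        return self.sets[1] + self.sets[2] + 1

    @property
    def game_no(self) -> int:
        return self.games[1] + self.games[2] + 1

    @property
    def sets_to_win(self) -> int:
        return self.best_of // 2 + 1

    def is_final_set(self) -> bool:
        return self.sets[1] == self.sets[2] == self.sets_to_win - 1

    def is_break_point(self) -> bool:
        """True iff the receiver wins the current game by winning this point."""
        if self.in_tiebreak:
            return False
        receiver = _other(self.server)
        return (self.points[receiver] >= 3
                and self.points[receiver] - self.points[self.server] >= 1)


@dataclass(frozen=True)
class StepResult:
    """Threshold events emitted by one :func:`advance` call."""

    game_victor: int = 0
    set_victor: int = 0
    match_victor: int = 0


def advance(state: ScoringState, point_winner: int) -> StepResult:
    """Apply one point to the score state; returns any game/set/match wins."""
    if state.finished:
        raise ValueError("cannot advance a finished match")
    if point_winner not in (1, 2):
        raise ValueError(f"point_winner must be 1 or 2, got {point_winner}")
    w, l = point_winner, _other(point_winner)
    state.points[w] += 1

    if state.in_tiebreak:
        if state.points[w] >= 7 and state.points[w] - state.points[l] >= 2:
            state.games[w] += 1  # 7-6
            return _win_set(state, w, after_tiebreak=True)
        if (state.points[1] + state.points[2]) % 2 == 1:
            state.server = _other(state.server)
        return StepResult()

    if state.points[w] >= 4 and state.points[w] - state.points[l] >= 2:
        state.games[w] += 1
        state.points = {1: 0, 2: 0}
        if state.games[w] >= 6 and state.games[w] - state.games[l] >= 2:
            return _win_set(state, w, after_tiebreak=False)
        state.server = _other(state.server)
        if state.games[1] == state.games[2] == 6:
            if state.final_set_tiebreak or not state.is_final_set():
                state.in_tiebreak = True
                state.tb_first_server = state.server
        return StepResult(game_victor=w)
    return StepResult()


def _win_set(state: ScoringState, w: int, *, after_tiebreak: bool) -> StepResult:
    state.sets[w] += 1
    state.points = {1: 0, 2: 0}
    state.games = {1: 0, 2: 0}
    state.server = _other(state.tb_first_server) if after_tiebreak else _other(state.server)
    state.in_tiebreak = False
    state.tb_first_server = 0
    if state.sets[w] == state.sets_to_win:
        state.finished = True
        state.winner = w
        return StepResult(game_victor=w, set_victor=w, match_victor=w)
    return StepResult(game_victor=w, set_victor=w)


def game_win_probability(p: float) -> float:
    """Closed-form P(server wins a standard game) from the per-point prob.

    Wins to love/15/30 plus the deuce continuation:
    ``p^4 (1 + 4q + 10 q^2) + 20 p^3 q^3 * p^2 / (1 - 2pq)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    q = 1.0 - p
    before_deuce = p ** 4 * (1.0 + 4.0 * q + 10.0 * q * q)
    if p in (0.0, 1.0):
        return float(p)
    from_deuce = p * p / (1.0 - 2.0 * p * q)
    return before_deuce + 20.0 * p ** 3 * q ** 3 * from_deuce


def calibrate_point_prob(target_game_prob: float) -> float:
    """Invert :func:`game_win_probability` by root finding (|residual| < 1e-10)."""
    if not 0.0 < target_game_prob < 1.0:
        raise ValueError("target game probability must be in (0, 1)")
    p = float(brentq(lambda x: game_win_probability(x) - target_game_prob,
                     1e-12, 1.0 - 1e-12, xtol=1e-14, rtol=8.9e-16))
    if abs(game_win_probability(p) - target_game_prob) >= 1e-10:
        raise RuntimeError("calibration did not converge")
    return p


def simulate_service_games(p: float, n_games: int, rng: np.random.Generator) -> np.ndarray:
    """Play ``n_games`` independent service games point-by-point (vectorised).

    Returns a boolean array: did the server win each game?  This is a
    mechanical simulation of the scoring rules, independent of the closed
    form, so it doubles as a Monte-Carlo oracle.
    """
    srv = np.zeros(n_games, dtype=np.int64)
    rcv = np.zeros(n_games, dtype=np.int64)
    done = np.zeros(n_games, dtype=bool)
    won = np.zeros(n_games, dtype=bool)
    for _ in range(100_000):
        active = ~done
        if not active.any():
            break
        draws = rng.random(int(active.sum())) < p
        srv[active] += draws
        rcv[active] += ~draws
        srv_done = active & (srv >= 4) & (srv - rcv >= 2)
        rcv_done = active & (rcv >= 4) & (rcv - srv >= 2)
        won |= srv_done
        done |= srv_done | rcv_done
    else:  # pragma: no cover - p extremely close to 0.5 forever in deuce
        raise RuntimeError("service games did not terminate")
    return won


@dataclass
class SimulationConfig:
    """Stochastic event model parameters for :func:`simulate_match`.

    Point endings are mutually exclusive by construction: the winner draw
    comes first, then exactly one of ace / serve winner / rally winner /
    unforced error / double fault (or a plain forced ending) explains the
    point.  Net approaches are attributed to the point winner with
    ``net_success_prob``, so the corpus net success rate converges there.
    """

    seed: int | None = None
    match_id: str = "sim-0001"
    best_of: int = 3
    court_type: str = "hard"
    serve_win_prob: tuple[float, float] = (0.645, 0.645)
    ace_given_serve_won: float = 0.12
    serve_winner_given_serve_won: float = 0.08
    winner_given_rally_won: float = 0.35
    unforced_given_rally_lost: float = 0.30
    double_fault_given_serve_lost: float = 0.10
    net_approach_rate: float = 0.25
    net_success_prob: float = 0.82
    gap_mean_seconds: float = 40.0
    gap_bounds: tuple[float, float] = (15.0, 180.0)
    final_set_tiebreak: bool = True
    momentum_feedback: float = 0.0

    def __post_init__(self) -> None:
        self.serve_win_prob = tuple(self.serve_win_prob)
        if self.court_type not in COURT_EFFECTS:
            raise ValueError(f"court_type must be one of {sorted(COURT_EFFECTS)}")
        if self.best_of not in (3, 5):
            raise ValueError("best_of must be 3 or 5")
        probs = (*self.serve_win_prob, self.ace_given_serve_won,
                 self.serve_winner_given_serve_won, self.winner_given_rally_won,
                 self.unforced_given_rally_lost, self.double_fault_given_serve_lost,
                 self.net_approach_rate, self.net_success_prob)
        if any(not 0.0 <= v <= 1.0 for v in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        ace_mult = COURT_EFFECTS[self.court_type]["ace_multiplier"]
        if ace_mult * self.ace_given_serve_won + self.serve_winner_given_serve_won > 1.0:
            raise ValueError("serve-ending probabilities exceed 1 within their branch")
        if self.gap_bounds[0] <= 0 or self.gap_bounds[0] > self.gap_bounds[1]:
            raise ValueError("gap_bounds must satisfy 0 < lo <= hi")

    def with_overrides(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class GroundTruth:
    """Generator-side annotations for oracle testing."""

    flags: list  # list[tuple[EventFlags, EventFlags]] aligned to points
    gaps: np.ndarray
    winner: int
    sets: tuple[int, int]
    counts: dict  # per player: aces, double_faults, winners, unf_errs, ...


def simulate_match(cfg: SimulationConfig) -> tuple[MatchRecord, GroundTruth]:
    """Generate one complete, schema-valid match with ground truth.

    Identical seeds yield identical output: a single seeded generator is
    consumed in a fixed per-point order (winner, ending type, net
    approach, rally/speed/distance numerics, inter-point gap).
    """
    rng = np.random.default_rng(cfg.seed)
    court = COURT_EFFECTS[cfg.court_type]
    p_ace = min(1.0, cfg.ace_given_serve_won * court["ace_multiplier"])

    state = ScoringState(best_of=cfg.best_of, final_set_tiebreak=cfg.final_set_tiebreak)
    match = MatchRecord(cfg.match_id, metadata={
        "court_type": cfg.court_type,
        "best_of": cfg.best_of,
        "tournament": "synthetic",
        "players": ("Player 1", "Player 2"),
    })
    truth_flags: list[tuple[EventFlags, EventFlags]] = []
    gaps: list[float] = []
    counts = {x: {"aces": 0, "double_faults": 0, "winners": 0, "unf_errs": 0,
                  "net_pts": 0, "net_pts_won": 0, "streak3_wins": 0,
                  "streak3_losses": 0, "break_pts": 0, "break_pts_won": 0}
              for x in (1, 2)}
    run = {1: 0, 2: 0}
    elapsed = 0.0
    point_no = 0

    while not state.finished:
        point_no += 1
        server = state.server
        receiver = _other(server)
        set_no, game_no = state.set_no, state.game_no

        p_serve = cfg.serve_win_prob[server - 1]
        if cfg.momentum_feedback:
            p_serve = float(np.clip(
                p_serve + cfg.momentum_feedback * np.tanh((run[server] - run[receiver]) / 3.0),
                0.0, 1.0))
        winner = server if rng.random() < p_serve else receiver
        loser = _other(winner)

        ace = serve_winner = shot_winner = double_fault = unforced = 0
        ending = rng.random()
        if winner == server:
            if ending < p_ace:
                ace = 1
            elif ending < p_ace + cfg.serve_winner_given_serve_won:
                serve_winner = 1
            else:
                rally_end = rng.random()
                if rally_end < cfg.winner_given_rally_won:
                    shot_winner = 1
                elif rally_end < cfg.winner_given_rally_won + cfg.unforced_given_rally_lost:
                    unforced = 1
        else:
            if ending < cfg.double_fault_given_serve_lost:
                double_fault = 1
            else:
                rally_end = rng.random()
                if rally_end < cfg.winner_given_rally_won:
                    shot_winner = 1
                elif rally_end < cfg.winner_given_rally_won + cfg.unforced_given_rally_lost:
                    unforced = 1

        net_player = 0
        if rng.random() < cfg.net_approach_rate and not ace and not double_fault:
            net_player = winner if rng.random() < cfg.net_success_prob else loser

        if ace or serve_winner:
            rally = 1
        elif double_fault:
            rally = 0
        else:
            rally = 2 + int(rng.poisson(court["rally_mean"]))
        speed = float(rng.normal(court["serve_speed_mean"], 8.0))
        dist = {x: round(rally * float(rng.uniform(1.5, 3.5)), 3) for x in (1, 2)}
        gap = float(np.clip(rng.exponential(cfg.gap_mean_seconds), *cfg.gap_bounds))
        elapsed += gap
        gaps.append(gap)

        bp = state.is_break_point()
        bp_won = bp and winner == receiver
        step = advance(state, winner)

        run[winner] += 1
        run[loser] = 0
        streak_win = run[winner] >= 3

        record = PointRecord(
            match_id=cfg.match_id, set_no=set_no, game_no=game_no,
            point_no=point_no, server=server, point_victor=winner,
            game_victor=step.game_victor, set_victor=step.set_victor,
            elapsed_seconds=round(elapsed, 3),
            rally_count=rally, serve_speed=round(speed, 1),
        )
        for x in (1, 2):
            setattr(record, f"ace_{x}", ace if x == server else 0)
            setattr(record, f"serve_winner_{x}", serve_winner if x == server else 0)
            setattr(record, f"winner_{x}", shot_winner if x == winner else 0)
            setattr(record, f"double_fault_{x}", double_fault if x == server else 0)
            setattr(record, f"unf_err_{x}", unforced if x == loser else 0)
            setattr(record, f"net_pt_{x}", int(net_player == x))
            setattr(record, f"net_pt_won_{x}", int(net_player == x and winner == x))
            setattr(record, f"break_pt_{x}", int(bp and x == receiver))
            setattr(record, f"break_pt_won_{x}", int(bp_won and x == receiver))
            setattr(record, f"distance_run_{x}", dist[x])
        match.points.append(record)

        pair = []
        for x in (1, 2):
            flags = EventFlags(
                serve_win=int(x == server == winner and (ace or serve_winner)),
                shot_win=int(x == winner and shot_winner),
                streak3_win=int(x == winner and streak_win),
                double_fault=int(x == server and double_fault),
                unforced_error=int(x == loser and unforced),
                streak3_loss=int(x == loser and streak_win),
                serving=x == server,
                is_break_point=bp and x == receiver,
                break_point_converted=bp_won and x == receiver,
            )
            pair.append(flags)
            c = counts[x]
            c["aces"] += int(x == server) * ace
            c["double_faults"] += int(x == server) * double_fault
            c["winners"] += flags.shot_win
            c["unf_errs"] += flags.unforced_error
            c["net_pts"] += int(net_player == x)
            c["net_pts_won"] += int(net_player == x and winner == x)
            c["streak3_wins"] += flags.streak3_win
            c["streak3_losses"] += flags.streak3_loss
            c["break_pts"] += int(flags.is_break_point)
            c["break_pts_won"] += int(flags.break_point_converted)
        truth_flags.append((pair[0], pair[1]))

    match.metadata["winner"] = state.winner
    truth = GroundTruth(
        flags=truth_flags,
        gaps=np.asarray(gaps),
        winner=state.winner,
        sets=(state.sets[1], state.sets[2]),
        counts=counts,
    )
    return match, truth


def simulate_corpus(
    n_matches: int,
    seed: int,
    base_cfg: SimulationConfig | None = None,
    skill_gap: float = 0.0,
    **overrides,
) -> list[tuple[MatchRecord, GroundTruth]]:
    """Generate an independent corpus of matches from one master seed.

    ``skill_gap`` shifts player 1's serve-point win probability up and
    player 2's down by the same amount, creating a controlled strength
    differential for power studies.
    """
    base_cfg = base_cfg or SimulationConfig()
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_matches):
        p1, p2 = base_cfg.serve_win_prob
        cfg = base_cfg.with_overrides(
            seed=int(master.integers(0, 2**63 - 1)),
            match_id=f"sim-{i + 1:04d}",
            serve_win_prob=(min(1.0, p1 + skill_gap), max(0.0, p2 - skill_gap)),
            **overrides,
        )
        out.append(simulate_match(cfg))
    return out
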