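"""Reading, writing and validation of point-by-point match tables.

Two CSV dialects are supported: ``"canonical"`` (this package's snake_case
schema, lossless round-trip) and ``"slam_pbp"`` (the column names used by
the public Grand Slam point-by-point repository).  Indicator columns are
tri-state: a missing column or empty cell is recorded as ``None`` (absent),
which downstream stages treat as "unknown", never as zero evidence.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("matchmomentum.match_io")

#: Binary per-player indicator stems (column = f"{stem}_{player}").
INDICATOR_STEMS = (
    "ace",
    "serve_winner",
    "winner",
    "double_fault",
    "unf_err",
    "net_pt",
    "net_pt_won",
    "break_pt",
    "break_pt_won",
)

MANDATORY_COLUMNS = ("match_id", "server", "point_victor")


@dataclass
class PointRecord:
    """One point of one match: identifiers, victors, timing, raw indicators.

    Players are indexed 1/2.  Binary indicators are tri-state:
    ``1``/``0`` when recorded, ``None`` when the source has no value.
    """

    match_id: str
    set_no: int = 1
    game_no: int = 1
    point_no: int = 1
    server: int = 1
    point_victor: int = 1
    game_victor: int = 0
    set_victor: int = 0
    elapsed_seconds: float | None = None
    ace_1: int | None = None
    ace_2: int | None = None
    serve_winner_1: int | None = None
    serve_winner_2: int | None = None
    winner_1: int | None = None
    winner_2: int | None = None
    double_fault_1: int | None = None
    double_fault_2: int | None = None
    unf_err_1: int | None = None
    unf_err_2: int | None = None
    net_pt_1: int | None = None
    net_pt_2: int | None = None
    net_pt_won_1: int | None = None
    net_pt_won_2: int | None = None
    break_pt_1: int | None = None
    break_pt_2: int | None = None
    break_pt_won_1: int | None = None
    break_pt_won_2: int | None = None
    distance_run_1: float | None = None
    distance_run_2: float | None = None
    rally_count: int | None = None
    serve_speed: float | None = None
    extras: dict = field(default_factory=dict)

    def indicator(self, stem: str, player: int) -> int | None:
        """Tri-state indicator value for one player (``None`` = absent)."""
        return getattr(self, f"{stem}_{player}")

    @property
    def receiver(self) -> int:
        return 2 if self.server == 1 else 1


@dataclass
class MatchRecord:
    """An ordered point sequence for one match plus corpus metadata."""

    match_id: str
    points: list[PointRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def court_type(self) -> str | None:
        return self.metadata.get("court_type")

    @property
    def best_of(self) -> int | None:
        return self.metadata.get("best_of")

    def set_numbers(self) -> list[int]:
        return sorted({p.set_no for p in self.points})


@dataclass(frozen=True)
class Violation:
    """A single data-invariant failure; violations are data, not exceptions."""

    rule: str
    point_no: int
    message: str


class DialectError(ValueError):
    """Unknown dialect name or missing mandatory columns."""


_POINT_FIELDS = [f.name for f in fields(PointRecord) if f.name != "extras"]

#: Canonical CSV column order (match metadata columns appended last).
CANONICAL_COLUMNS = _POINT_FIELDS + ["court_type", "best_of"]

#: slam_pbp -> canonical column mapping (the shipped dialect table).
SLAM_PBP_MAP = {
    "match_id": "match_id",
    "ElapsedTime": "elapsed_seconds",
    "SetNo": "set_no",
    "GameNo": "game_no",
    "PointNumber": "point_no",
    "PointServer": "server",
    "PointWinner": "point_victor",
    "GameWinner": "game_victor",
    "SetWinner": "set_victor",
    "P1Ace": "ace_1",
    "P2Ace": "ace_2",
    "P1Winner": "winner_1",
    "P2Winner": "winner_2",
    "P1DoubleFault": "double_fault_1",
    "P2DoubleFault": "double_fault_2",
    "P1UnfErr": "unf_err_1",
    "P2UnfErr": "unf_err_2",
    "P1NetPoint": "net_pt_1",
    "P2NetPoint": "net_pt_2",
    "P1NetPointWon": "net_pt_won_1",
    "P2NetPointWon": "net_pt_won_2",
    "P1BreakPoint": "break_pt_1",
    "P2BreakPoint": "break_pt_2",
    "P1BreakPointWon": "break_pt_won_1",
    "P2BreakPointWon": "break_pt_won_2",
    "P1DistanceRun": "distance_run_1",
    "P2DistanceRun": "distance_run_2",
    "RallyCount": "rally_count",
    "Speed_KMH": "serve_speed",
}

DIALECTS = {"canonical", "slam_pbp"}

_INT_FIELDS = {"set_no", "game_no", "point_no", "server", "point_victor",
               "game_victor", "set_victor", "rally_count"}
_FLOAT_FIELDS = {"elapsed_seconds", "distance_run_1", "distance_run_2", "serve_speed"}
_INDICATOR_FIELDS = {f"{stem}_{x}" for stem in INDICATOR_STEMS for x in (1, 2)}


def parse_clock(value: str) -> float | None:
    """Parse an ``H:MM:SS`` cumulative clock string to seconds.

    Plain numeric strings pass through; anything else returns ``None``.
    """
    text = str(value).strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        pass
    parts = text.split(":")
    if len(parts) != 3:
        return None
    try:
        h, m, s = (float(p) for p in parts)
    except ValueError:
        return None
    if m < 0 or s < 0 or h < 0:
        return None
    return h * 3600.0 + m * 60.0 + s


def _convert(name: str, raw: str, *, dialect: str, row_no: int) -> object:
    if raw == "":
        return None
    if name == "elapsed_seconds":
        if dialect == "slam_pbp":
            parsed = parse_clock(raw)
            if parsed is None:
                logger.warning("row %d: unparseable clock %r; elapsed missing", row_no, raw)
            return parsed
        try:
            return float(raw)
        except ValueError:
            logger.warning("row %d: unparseable elapsed_seconds %r", row_no, raw)
            return None
    if name in _INT_FIELDS:
        return int(float(raw))
    if name in _FLOAT_FIELDS:
        return float(raw)
    if name in _INDICATOR_FIELDS:
        return int(float(raw))
    return raw


def read_points(path, dialect: str = "canonical") -> list[MatchRecord]:
    """Read a point-by-point CSV into one :class:`MatchRecord` per match.

    Points of each match are ordered by ``point_no``; unknown columns are
    preserved in ``PointRecord.extras``.  Missing indicator columns become
    ``None`` (absent), not zero.

    Raises :class:`DialectError` when the dialect is unknown or a mandatory
    column (match_id, server, point_victor) is missing.
    """
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "slam_pbp":
        frame = frame.rename(columns=SLAM_PBP_MAP)

    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise DialectError(f"missing mandatory column(s): {', '.join(missing)}")

    known = set(_POINT_FIELDS) | {"court_type", "best_of"}
    extra_cols = [c for c in frame.columns if c not in known]

    matches: dict[str, MatchRecord] = {}
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        data = dict(zip(frame.columns, row))
        kwargs: dict = {"match_id": str(data["match_id"])}
        for name in _POINT_FIELDS[1:]:
            if name in data:
                value = _convert(name, str(data[name]), dialect=dialect, row_no=row_no)
                if value is not None:
                    kwargs[name] = value
        record = PointRecord(**kwargs)
        if "point_no" not in data or str(data["point_no"]) == "":
            record.point_no = sum(len(m.points) for m in matches.values()) + 1
        record.extras = {c: data[c] for c in extra_cols if str(data[c]) != ""}

        match = matches.get(record.match_id)
        if match is None:
            match = matches[record.match_id] = MatchRecord(record.match_id)
        match.points.append(record)
        for meta in ("court_type", "best_of"):
            if meta in data and str(data[meta]) != "" and meta not in match.metadata:
                raw = str(data[meta])
                match.metadata[meta] = int(raw) if meta == "best_of" else raw

    for match in matches.values():
        match.points.sort(key=lambda p: p.point_no)
    return list(matches.values())


def _format(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return repr(value) if value != int(value) else str(int(value))
    return str(value)


def write_points(matches: Iterable[MatchRecord], path) -> object:
    """Write matches as a canonical-dialect CSV (UTF-8, LF, RFC-4180).

    Round-trips losslessly with ``read_points(path, "canonical")``; writing
    the re-read collection again is byte-identical.
    """
    matches = list(matches)
    extra_cols = sorted({key for m in matches for p in m.points for key in p.extras})
    header = CANONICAL_COLUMNS + extra_cols
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(header)
        for match in matches:
            court = match.metadata.get("court_type")
            best_of = match.metadata.get("best_of")
            for point in match.points:
                row = [_format(getattr(point, name)) for name in _POINT_FIELDS]
                row.append(_format(court))
                row.append(_format(best_of))
                row.extend(_format(point.extras.get(c)) for c in extra_cols)
                writer.writerow(row)
    return path


def validate_match(match: MatchRecord) -> list[Violation]:
    """Check all point- and match-level invariants; return the failures.

    Violations are returned as data (rule name + point number) rather than
    raised, so flawed rows can be kept and flagged.
    """
    out: list[Violation] = []

    def bad(rule: str, point: PointRecord, message: str) -> None:
        out.append(Violation(rule, point.point_no, message))

    prev: PointRecord | None = None
    for point in match.points:
        if point.match_id != match.match_id:
            bad("match_id_consistent", point, f"point match_id {point.match_id!r} != {match.match_id!r}")
        if point.server not in (1, 2):
            bad("server_in_1_2", point, f"server={point.server}")
        if point.point_victor not in (1, 2):
            bad("point_victor_in_1_2", point, f"point_victor={point.point_victor}")
        if point.game_victor not in (0, 1, 2):
            bad("game_victor_in_0_1_2", point, f"game_victor={point.game_victor}")
        if point.set_victor not in (0, 1, 2):
            bad("set_victor_in_0_1_2", point, f"set_victor={point.set_victor}")
        if point.elapsed_seconds is not None and point.elapsed_seconds < 0:
            bad("elapsed_nonnegative", point, f"elapsed_seconds={point.elapsed_seconds}")

        if prev is not None:
            if point.point_no <= prev.point_no:
                bad("point_no_increasing", point,
                    f"point_no {point.point_no} after {prev.point_no}")
            if point.set_no < prev.set_no:
                bad("set_no_nondecreasing", point,
                    f"set_no {point.set_no} after {prev.set_no}")
            if prev.game_victor != 0 and (point.set_no, point.game_no) == (prev.set_no, prev.game_no):
                bad("game_victor_ends_game", prev,
                    "game_victor set but the game continues on the next point")

        server = point.server if point.server in (1, 2) else 1
        if point.indicator("double_fault", server) == 1 and point.point_victor == server:
            bad("double_fault_loses_point", point, "double fault only by server, point to opponent")
        receiver = 2 if server == 1 else 1
        if point.indicator("double_fault", receiver) == 1:
            bad("double_fault_server_only", point, "double fault flagged for the receiver")
        if point.indicator("ace", server) == 1 and point.point_victor != server:
            bad("ace_implies_server_wins", point, "ace implies server wins point")
        if point.indicator("ace", receiver) == 1:
            bad("ace_server_only", point, "ace flagged for the receiver")
        for x in (1, 2):
            if point.indicator("net_pt_won", x) == 1 and point.indicator("net_pt", x) != 1:
                bad("net_pt_won_implies_net_pt", point, f"net_pt_won_{x} without net_pt_{x}")
            if point.indicator("break_pt_won", x) == 1 and point.indicator("break_pt", x) != 1:
                bad("break_pt_won_implies_break_pt", point, f"break_pt_won_{x} without break_pt_{x}")
        prev = point
    return out


def concat_points(matches: Sequence[MatchRecord]) -> pd.DataFrame:
    """Flatten a corpus into one DataFrame (canonical column names)."""
    rows = []
    for match in matches:
        for point in match.points:
            row = {name: getattr(point, name) for name in _POINT_FIELDS}
            row["court_type"] = match.metadata.get("court_type")
            rows.append(row)
    return pd.DataFrame(rows)
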