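"""Coded-event tables and their rasterization into 1 Hz level/tier series.

A coded event is one timed episode of behavior in a single stream
("gesture" or "speech"), optionally carrying a complexity level 1-7.
Events are rasterized onto a 1-second grid: each second-bin [t, t+1)
carries the level of the event covering the majority (>= 0.5 s) of that
bin, and 0 where no leveled event does.

Levels map onto three tiers: 1-3 -> tier 1 (sensorimotor),
4-6 -> tier 2 (representational), 7 -> tier 3 (abstract), 0 -> 0.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STREAMS = ("gesture", "speech")

#: level -> tier lookup (index by level 0..7)
LEVEL_TO_TIER = np.array([0, 1, 1, 1, 2, 2, 2, 3], dtype=np.int64)

TIER_NAMES = {0: "none", 1: "sensorimotor", 2: "representational", 3: "abstract"}

EVENTS_HEADER = ["child_id", "stream", "start_s", "end_s", "category", "level"]
META_HEADER = [
    "child_id",
    "grade",
    "age_months",
    "math_score",
    "language_score",
    "avg_past_score",
]


class EventParseError(ValueError):
    """A row of an events file could not be parsed."""


class EventValidationError(ValueError):
    """Parsed events violate an invariant (ordering, overlap, range)."""


@dataclass(frozen=True)
class CodedEvent:
    """One timed, leveled behavioral episode in one stream."""

    stream: str
    start_s: float
    end_s: float
    category: str = ""
    level: int | None = None

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise EventValidationError(
                f"stream must be one of {STREAMS}, got {self.stream!r}"
            )
        if not self.end_s > self.start_s:
            raise EventValidationError(
                f"end_s must exceed start_s (got [{self.start_s}, {self.end_s}))"
            )
        if self.start_s < 0:
            raise EventValidationError(f"start_s must be non-negative, got {self.start_s}")
        if self.level is not None and self.level not in range(1, 8):
            raise EventValidationError(f"level must be in 1..7 or None, got {self.level}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SkillSeries:
    """1 Hz series of skill levels (0 = no event) for one stream of one child."""

    values: np.ndarray
    child_id: str = ""
    stream: str = "gesture"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 1 or arr.size < 1:
            raise EventValidationError("series must be 1-D with length >= 1")
        if arr.min() < 0 or arr.max() > 7:
            raise EventValidationError("skill levels must lie in 0..7")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TierSeries:
    """1 Hz series of tiers (0 none, 1 S, 2 R, 3 A); aligned with its SkillSeries."""

    values: np.ndarray
    child_id: str = ""
    stream: str = "gesture"
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 1 or arr.size < 1:
            raise EventValidationError("series must be 1-D with length >= 1")
        if arr.min() < 0 or arr.max() > 3:
            raise EventValidationError("tiers must lie in 0..3")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ChildMeta:
    """Per-child metadata row: grade, age, and school outcome scores."""

    child_id: str
    grade: str
    age_months: int
    math_score: float | None = None
    language_score: float | None = None
    avg_past_score: float | None = None

    def __post_init__(self) -> None:
        if self.grade not in ("KG", "1"):
            raise EventValidationError(f"grade must be 'KG' or '1', got {self.grade!r}")
        for name in ("math_score", "language_score"):
            v = getattr(self, name)
            if v is not None and not (1 <= v <= 5):
                raise EventValidationError(f"{name} must be in [1, 5], got {v}")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def read_events(path: str | Path) -> dict[str, list[CodedEvent]]:
    """Read an events CSV, returning ``{child_id: [CodedEvent, ...]}``.

    Dialect: UTF-8, comma-separated, header
    ``child_id,stream,start_s,end_s,category,level``; an empty ``level``
    field means the event carries no skill level.

    Events are returned sorted by start time within each child. Raises
    :class:`EventParseError` naming the offending line for malformed rows,
    and :class:`EventValidationError` naming both rows for overlapping
    events within one stream of one child.
    """
    path = Path(path)
    per_child: dict[str, list[tuple[int, CodedEvent]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != EVENTS_HEADER:
            raise EventParseError(
                f"{path}: expected header {','.join(EVENTS_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 6:
                raise EventParseError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
            child_id, stream, start_s, end_s, category, level = (c.strip() for c in row)
            try:
                ev = CodedEvent(
                    stream=stream,
                    start_s=float(start_s),
                    end_s=float(end_s),
                    category=category,
                    level=int(level) if level else None,
                )
            except (ValueError, TypeError) as exc:
                raise EventParseError(f"{path}:{lineno}: {exc}") from exc
            per_child.setdefault(child_id, []).append((lineno, ev))

    out: dict[str, list[CodedEvent]] = {}
    for child_id, rows in per_child.items():
        rows.sort(key=lambda r: (r[1].stream, r[1].start_s))
        for (ln_a, a), (ln_b, b) in zip(rows, rows[1:]):
            if a.stream == b.stream and b.start_s < a.end_s:
                raise EventValidationError(
                    f"{path}: overlapping {a.stream} events for child {child_id!r} "
                    f"at lines {ln_a} ([{a.start_s}, {a.end_s})) and "
                    f"{ln_b} ([{b.start_s}, {b.end_s}))"
                )
        out[child_id] = sorted((ev for _, ev in rows), key=lambda e: e.start_s)
    return out


def write_events(events: dict[str, list[CodedEvent]], path: str | Path) -> None:
    """Write ``{child_id: events}`` in the events CSV dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENTS_HEADER)
        for child_id in events:
            for ev in sorted(events[child_id], key=lambda e: (e.stream, e.start_s)):
                writer.writerow(
                    [
                        child_id,
                        ev.stream,
                        _fmt_num(ev.start_s),
                        _fmt_num(ev.end_s),
                        ev.category,
                        "" if ev.level is None else ev.level,
                    ]
                )


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_metadata(path: str | Path) -> dict[str, ChildMeta]:
    """Read the child-metadata CSV; missing scores are empty fields."""
    df = pd.read_csv(path, dtype={"child_id": str, "grade": str})
    missing = set(META_HEADER) - set(df.columns)
    if missing:
        raise EventParseError(f"{path}: metadata file missing columns {sorted(missing)}")
    out: dict[str, ChildMeta] = {}
    for _, row in df.iterrows():
        out[row["child_id"]] = ChildMeta(
            child_id=row["child_id"],
            grade=str(row["grade"]),
            age_months=int(row["age_months"]),
            math_score=None if pd.isna(row["math_score"]) else float(row["math_score"]),
            language_score=(
                None if pd.isna(row["language_score"]) else float(row["language_score"])
            ),
            avg_past_score=(
                None if pd.isna(row["avg_past_score"]) else float(row["avg_past_score"])
            ),
        )
    return out


def write_metadata(meta: Iterable[ChildMeta], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(META_HEADER)
        for m in meta:
            writer.writerow(
                [
                    m.child_id,
                    m.grade,
                    m.age_months,
                    "" if m.math_score is None else _fmt_num(m.math_score),
                    "" if m.language_score is None else _fmt_num(m.language_score),
                    "" if m.avg_past_score is None else _fmt_num(m.avg_past_score),
                ]
            )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize(
    events: Sequence[CodedEvent],
    duration_s: int,
    child_id: str = "",
    stream: str | None = None,
) -> SkillSeries:
    """Rasterize single-stream events onto a 1 Hz grid of length ``duration_s``.

    Bins are half-open ``[t, t+1)``, 0-based. A bin carries the level of
    the event overlapping it by at least 0.5 s (majority rule); exact
    0.5/0.5 ties between two events go to the later-starting one. Bins
    with no leveled event, and events without a level, contribute 0.
    """
    streams = {e.stream for e in events}
    if len(streams) > 1:
        raise EventValidationError(f"events span multiple streams: {sorted(streams)}")
    if stream is None:
        stream = streams.pop() if streams else "gesture"
    duration_s = int(duration_s)
    max_end = max((e.end_s for e in events), default=0.0)
    if duration_s < math.ceil(max_end):
        raise EventValidationError(
            f"duration_s={duration_s} shorter than ceil(max end) = {math.ceil(max_end)}"
        )
    if duration_s < 1:
        raise EventValidationError("duration_s must be >= 1")

    values = np.zeros(duration_s, dtype=np.int64)
    # (overlap, start_s) of the current claimant per bin; later start wins 0.5 ties
    claim: dict[int, tuple[float, float]] = {}
    for ev in events:
        if ev.level is None:
            continue
        first = int(math.floor(ev.start_s))
        last = min(int(math.ceil(ev.end_s)), duration_s)
        for t in range(first, last):
            overlap = min(ev.end_s, t + 1) - max(ev.start_s, t)
            if overlap < 0.5:
                continue
            prev = claim.get(t)
            if prev is None or overlap > prev[0] or (overlap == prev[0] and ev.start_s > prev[1]):
                claim[t] = (overlap, ev.start_s)
                values[t] = ev.level
    return SkillSeries(values=values, child_id=child_id, stream=stream)


def to_tiers(series: SkillSeries) -> TierSeries:
    """Map a skill-level series elementwise onto tiers (see LEVEL_TO_TIER)."""
    return TierSeries(
        values=LEVEL_TO_TIER[series.values],
        child_id=series.child_id,
        stream=series.stream,
        t0_s=series.t0_s,
    )


def to_events(series: SkillSeries, category: str = "") -> list[CodedEvent]:
    """Inverse of :func:`rasterize` for whole-second-aligned series.

    Each maximal run of a constant nonzero level becomes one event.
    """
    events: list[CodedEvent] = []
    vals = series.values
    start = None
    for t in range(len(vals) + 1):
        v = vals[t] if t < len(vals) else 0
        if start is not None and (t == len(vals) or v != vals[start]):
            if vals[start] != 0:
                events.append(
                    CodedEvent(
                        stream=series.stream,
                        start_s=float(start),
                        end_s=float(t),
                        category=category,
                        level=int(vals[start]),
                    )
                )
            start = t if t < len(vals) and v != 0 else None
        if start is None and t < len(vals) and v != 0:
            start = t
    return events


def series_frame(gesture: SkillSeries, speech: SkillSeries) -> pd.DataFrame:
    """Tabulate a child's two rasterized streams with their tier mappings."""
    if len(gesture) != len(speech):
        raise EventValidationError("gesture and speech series must share a duration")
    return pd.DataFrame(
        {
            "t_s": np.arange(len(gesture)),
            "gesture_level": gesture.values,
            "speech_level": speech.values,
            "gesture_tier": to_tiers(gesture).values,
            "speech_tier": to_tiers(speech).values,
        }
    )


def rasterize_child(
    events: Sequence[CodedEvent], child_id: str = "", duration_s: int | None = None
) -> tuple[SkillSeries, SkillSeries]:
    """Rasterize one child's gesture and speech events to a common duration.

    Both streams are rasterized to the same length (the ceiling of the
    latest event end across both streams, or ``duration_s`` if given), so
    the downstream cross-recurrence plot is square.
    """
    by_stream: dict[str, list[CodedEvent]] = {s: [] for s in STREAMS}
    for ev in events:
        by_stream[ev.stream].append(ev)
    if duration_s is None:
        max_end = max((e.end_s for e in events), default=1.0)
        duration_s = max(1, int(math.ceil(max_end)))
    g = rasterize(by_stream["gesture"], duration_s, child_id=child_id, stream="gesture")
    s = rasterize(by_stream["speech"], duration_s, child_id=child_id, stream="speech")
    return g, s
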