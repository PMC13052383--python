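"""Domain types for segments, events, timestamps, timelines, correlation
matrices, plus JSONL/TSV readers and writers.

All file formats are plain UTF-8 text: segments and timelines are JSONL
(one record per line), the historical-event table is 3-column TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TimeKind",
    "NarrativeSegment",
    "TimeStamp",
    "StructuredEvent",
    "EventFeatureMatrix",
    "CorrelationMatrix",
    "TimelineEntry",
    "Timeline",
    "HistoricalEvent",
    "ParseError",
    "ValidationError",
    "read_segments",
    "write_segments",
    "write_timeline",
    "read_timeline",
    "read_historical_db",
    "write_historical_db",
    "read_events",
    "write_events",
]


class ParseError(ValueError):
    """A file could not be parsed under the declared format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


class TimeKind(str, Enum):
    ABSOLUTE = "absolute"
    RELATIVE_RESOLVED = "relative_resolved"
    HISTORICAL_MAPPED = "historical_mapped"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class NarrativeSegment:
    """One transcribed fragment of a narrative session.

    ``sequence_index`` records the order within the original transcript and
    drives narrative-proximity tie-breaking downstream.
    """

    segment_id: str
    session_id: str
    sequence_index: int
    text: str

    def __post_init__(self) -> None:
        if self.sequence_index < 0:
            raise ValidationError(
                f"segment {self.segment_id!r}: sequence_index must be >= 0"
            )
        if not self.text.strip():
            raise ValidationError(f"segment {self.segment_id!r}: empty text")


@dataclass(frozen=True)
class TimeStamp:
    """A normalized temporal value.

    ``value`` is a calendar year (int) or ISO date string; it is absent
    exactly when ``kind`` is unknown.  ``flagged_for_review`` marks
    historical anchors in the human-verification confidence band.
    """

    kind: TimeKind = TimeKind.UNKNOWN
    value: int | str | None = None
    confidence: float = 1.0
    flagged_for_review: bool = False

    def __post_init__(self) -> None:
        if (self.kind is TimeKind.UNKNOWN) != (self.value is None):
            raise ValidationError("kind=unknown iff value is absent")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError("confidence must lie in [0, 1]")
        if self.flagged_for_review and not (0.70 <= self.confidence <= 0.85):
            raise ValidationError(
                "flagged_for_review requires confidence in [0.70, 0.85]"
            )

    @property
    def year(self) -> int | None:
        """Year granularity of ``value`` (None when unknown)."""
        if self.value is None:
            return None
        if isinstance(self.value, int):
            return self.value
        return int(str(self.value)[:4])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "value": self.value,
            "confidence": self.confidence,
            "flagged_for_review": self.flagged_for_review,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TimeStamp":
        return cls(
            kind=TimeKind(d.get("kind", "unknown")),
            value=d.get("value"),
            confidence=float(d.get("confidence", 1.0)),
            flagged_for_review=bool(d.get("flagged_for_review", False)),
        )


UNKNOWN_TIME = TimeStamp()


@dataclass
class StructuredEvent:
    """The 6-element structured representation of one life event:
    type, trigger, time, location, participants, summary."""

    event_id: str
    event_type: str
    trigger: str
    time: TimeStamp = field(default_factory=TimeStamp)
    location: str | None = None
    participants: list[str] = field(default_factory=list)
    summary: list[str] = field(default_factory=list)
    source_segment_ids: list[str] = field(default_factory=list)
    time_expression: str | None = None  # raw token prior to normalization

    def __post_init__(self) -> None:
        if not self.trigger:
            raise ValidationError(f"event {self.event_id!r}: empty trigger")
        if len(self.summary) > 3:
            raise ValidationError(
                f"event {self.event_id!r}: summary longer than 3 sentences"
            )

    def with_time(self, ts: TimeStamp) -> "StructuredEvent":
        return replace(self, time=ts)

    def text(self) -> str:
        """Concatenated surface form used for embedding and anchoring."""
        parts = [self.trigger + "."]
        parts.extend(self.summary)
        if self.location:
            parts.append(self.location + ".")
        if self.participants:
            parts.append(" ".join(self.participants) + ".")
        return " ".join(parts)

    def to_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "event_type": self.event_type,
            "trigger": self.trigger,
            "time": self.time.to_dict(),
            "location": self.location,
            "participants": list(self.participants),
            "summary": list(self.summary),
            "source_segment_ids": list(self.source_segment_ids),
            "time_expression": self.time_expression,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StructuredEvent":
        return cls(
            event_id=d["event_id"],
            event_type=d["event_type"],
            trigger=d["trigger"],
            time=TimeStamp.from_dict(d.get("time", {"kind": "unknown"})),
            location=d.get("location"),
            participants=list(d.get("participants", [])),
            summary=list(d.get("summary", [])),
            source_segment_ids=list(d.get("source_segment_ids", [])),
            time_expression=d.get("time_expression"),
        )


class EventFeatureMatrix:
    """The n x m matrix of event feature vectors, rows aligned with
    ``event_ids``."""

    def __init__(self, event_ids: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if matrix.shape[0] != len(event_ids):
            raise ValidationError("row count must match number of event ids")
        if matrix.shape[0] < 1:
            raise ValidationError("need at least one event")
        if np.any(~np.isfinite(matrix)):
            raise ValidationError("feature matrix contains non-finite entries")
        if np.any(np.all(matrix == 0.0, axis=1)):
            raise ValidationError("feature matrix contains an all-zero row")
        if len(set(event_ids)) != len(event_ids):
            raise ValidationError("duplicate event ids")
        self.event_ids = list(event_ids)
        self.matrix = matrix

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    def row(self, event_id: str) -> np.ndarray:
        return self.matrix[self.event_ids.index(event_id)]


class CorrelationMatrix:
    """Symmetric n x n event relevance with unit diagonal, entries in [0, 1].

    Pairs never co-clustered by either clustering view carry exactly 0.
    """

    def __init__(self, event_ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(event_ids)
        if values.shape != (n, n):
            raise ValidationError(f"expected a {n}x{n} matrix")
        if np.any(values < -1e-9) or np.any(values > 1.0 + 1e-9):
            raise ValidationError("correlation values must lie in [0, 1]")
        if not np.allclose(values, values.T, atol=1e-8):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-8):
            raise ValidationError("correlation diagonal must be 1")
        self.event_ids = list(event_ids)
        self.values = np.clip(values, 0.0, 1.0)

    def rel(self, a: str, b: str) -> float:
        i = self.event_ids.index(a)
        j = self.event_ids.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("\t".join(["event_id"] + self.event_ids) + "\n")
            for eid, row in zip(self.event_ids, self.values):
                fh.write(eid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CorrelationMatrix":
        path = Path(path)
        lines = path.read_text(encoding="utf-8").splitlines()
        if not lines:
            raise ParseError(f"{path}: empty correlation file")
        ids = lines[0].rstrip("\n").split("\t")[1:]
        rows = []
        for lineno, line in enumerate(lines[1:], start=2):
            cells = line.split("\t")
            if len(cells) != len(ids) + 1:
                raise ParseError(f"{path}:{lineno}: wrong column count")
            rows.append([float(c) for c in cells[1:]])
        return cls(ids, np.array(rows))


@dataclass(frozen=True)
class TimelineEntry:
    event_id: str
    time: TimeStamp
    anchored: bool
    inserted_position_score: float | None = None


class Timeline:
    """Ordered sequence of timeline entries.

    Positions are 0-based; the virtual start/end nodes used by the
    insertion formula are positional conventions and never stored.
    Anchored entries must be in non-decreasing timestamp order.
    """

    def __init__(self, entries: Iterable[TimelineEntry] = ()):
        self.entries: list[TimelineEntry] = list(entries)
        self._validate()

    def _validate(self) -> None:
        seen = set()
        for e in self.entries:
            if e.event_id in seen:
                raise ValidationError(f"duplicate timeline event {e.event_id!r}")
            seen.add(e.event_id)
        years = [e.time.year for e in self.entries if e.anchored]
        for a, b in zip(years, years[1:]):
            if a is not None and b is not None and a > b:
                raise ValidationError("anchored entries out of chronological order")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, Timeline) and self.entries == other.entries

    def event_ids(self) -> list[str]:
        return [e.event_id for e in self.entries]

    def insert(self, position: int, entry: TimelineEntry) -> None:
        self.entries.insert(position, entry)
        self._validate()


@dataclass(frozen=True)
class HistoricalEvent:
    """One row of the historical anchor table."""

    name: str
    year: int
    description: str

    def __post_init__(self) -> None:
        if not 1900 <= self.year <= 2100:
            raise ValidationError(
                f"historical event {self.name!r}: year {self.year} outside 1900-2100"
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_segments(path: str | Path, format: str = "jsonl") -> list[NarrativeSegment]:
    """Read narrative segments from ``path``.

    ``format="jsonl"`` expects one object per line with keys segment_id,
    session_id, text and optional sequence_index; ``format="plain_text"``
    treats each non-blank line as one segment.  When sequence_index is
    absent it is assigned in file order.
    """
    path = Path(path)
    segments: list[NarrativeSegment] = []
    seen_ids: set[str] = set()
    if format == "plain_text":
        idx = 0
        for lineno, line in enumerate(
            path.read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip():
                continue
            sid = f"seg-{idx:06d}"
            segments.append(
                NarrativeSegment(
                    segment_id=sid, session_id="session-0",
                    sequence_index=idx, text=line,
                )
            )
            idx += 1
        return segments
    if format != "jsonl":
        raise ValueError(f"unknown segment format {format!r}")
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSON record: {exc}")
            try:
                seg = NarrativeSegment(
                    segment_id=str(rec["segment_id"]),
                    session_id=str(rec.get("session_id", "session-0")),
                    sequence_index=int(rec.get("sequence_index", len(segments))),
                    text=str(rec["text"]),
                )
            except KeyError as exc:
                raise ParseError(f"{path}:{lineno}: missing field {exc}")
            if seg.segment_id in seen_ids:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate segment_id {seg.segment_id!r}"
                )
            seen_ids.add(seg.segment_id)
            segments.append(seg)
    return segments


def write_segments(segments: Sequence[NarrativeSegment], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in segments:
            fh.write(
                json.dumps(
                    {
                        "segment_id": s.segment_id,
                        "session_id": s.session_id,
                        "sequence_index": s.sequence_index,
                        "text": s.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_timeline(
    timeline: Timeline,
    events: Sequence[StructuredEvent],
    path: str | Path,
) -> None:
    """Write a timeline as JSONL, one record per position."""
    by_id = {e.event_id: e for e in events}
    for entry in timeline:
        if entry.event_id not in by_id:
            raise ValidationError(f"timeline references unknown event {entry.event_id!r}")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# timeline: position, event_id, timestamp, anchored, summary\n")
        for pos, entry in enumerate(timeline):
            ev = by_id[entry.event_id]
            fh.write(
                json.dumps(
                    {
                        "position": pos,
                        "event_id": entry.event_id,
                        "timestamp": entry.time.to_dict(),
                        "anchored": entry.anchored,
                        "inserted_position_score": entry.inserted_position_score,
                        "summary": ev.summary,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_timeline(path: str | Path) -> Timeline:
    entries = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSON record: {exc}")
            entries.append(
                TimelineEntry(
                    event_id=rec["event_id"],
                    time=TimeStamp.from_dict(rec["timestamp"]),
                    anchored=bool(rec["anchored"]),
                    inserted_position_score=rec.get("inserted_position_score"),
                )
            )
    return Timeline(entries)


def read_historical_db(path: str | Path) -> list[HistoricalEvent]:
    """Read the 3-column (name, year, description) TSV anchor table."""
    path = Path(path)
    rows: list[HistoricalEvent] = []
    names: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
            name, year_s, desc = cells
            try:
                year = int(year_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer year {year_s!r}")
            if name in names:
                raise ValidationError(f"{path}:{lineno}: duplicate name {name!r}")
            names.add(name)
            rows.append(HistoricalEvent(name=name, year=year, description=desc))
    return rows


def write_historical_db(rows: Sequence[HistoricalEvent], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in rows:
            fh.write(f"{r.name}\t{r.year}\t{r.description}\n")


def read_events(path: str | Path) -> list[StructuredEvent]:
    events = []
    seen: set[str] = set()
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSON record: {exc}")
            ev = StructuredEvent.from_dict(rec)
            if ev.event_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate event_id")
            seen.add(ev.event_id)
            events.append(ev)
    return events


def write_events(events: Sequence[StructuredEvent], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in events:
            fh.write(json.dumps(e.to_dict(), ensure_ascii=False) + "\n")
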