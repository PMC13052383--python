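"""Temporal normalization, historical anchoring, backbone construction,
and relevance-based greedy insertion of undated events.

Dated events are sorted chronologically as the timeline backbone; each
undated event u is inserted at the gap i (0 <= i <= n, with virtual start
and end nodes) maximizing

    alpha * Rel(e_i, u) + (1 - alpha) * Rel(u, e_{i+1})

where relevance to a virtual node is 0.  Exact ties are broken toward the
gap whose flanking real event is closest to u in original transcript
order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from care_et.event_model import (
    CorrelationMatrix,
    HistoricalEvent,
    StructuredEvent,
    TimeKind,
    TimeStamp,
    Timeline,
    TimelineEntry,
    ValidationError,
)
from care_et.extraction import Embedder, cosine

__all__ = [
    "AnchorMatch",
    "normalize_time",
    "match_anchor",
    "build_backbone",
    "insert_undated",
    "build_timeline",
]

ACCEPT_THRESHOLD = 0.85
FLAG_THRESHOLD = 0.70


@dataclass(frozen=True)
class AnchorMatch:
    event_id: str
    historical_event: HistoricalEvent
    similarity: float

    def __post_init__(self) -> None:
        if self.similarity <= FLAG_THRESHOLD:
            raise ValidationError("anchor matches below the flag threshold are dropped")


_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "fifteen": 15, "twenty": 20, "thirty": 30, "forty": 40,
    "fifty": 50, "sixty": 60,
}
_CJK_DIGITS = {"一": 1, "二": 2, "两": 2, "三": 3, "四": 4, "五": 5,
               "六": 6, "七": 7, "八": 8, "九": 9, "十": 10}

_YEAR_RE = re.compile(r"\b(1[89]\d{2}|20\d{2})\b")
_AGO_RE = re.compile(r"\b(\d+|[a-z]+)\s+years?\s+ago\b", re.IGNORECASE)
_CJK_AGO_RE = re.compile(r"([0-9一二两三四五六七八九十]+)年前")


def _parse_count(token: str) -> int | None:
    if token.isdigit():
        return int(token)
    if token.lower() in _NUMBER_WORDS:
        return _NUMBER_WORDS[token.lower()]
    if all(ch in _CJK_DIGITS for ch in token):
        if len(token) == 1:
            return _CJK_DIGITS[token]
        if len(token) == 2 and token[0] == "十":
            return 10 + _CJK_DIGITS[token[1]]
        if len(token) == 2 and token[1] == "十":
            return _CJK_DIGITS[token[0]] * 10
    return None


def normalize_time(raw_expression: str, narration_reference_year: int) -> TimeStamp:
    """Standardize one temporal expression to a TimeStamp.

    Four-digit years become absolute; "N years ago" (and the Chinese
    "N年前") resolve against the narration reference year; everything
    else, including vague adverbs like "back then", stays unknown so the
    event is sequenced by narrative flow instead.
    """
    if not raw_expression or not raw_expression.strip():
        raise ValueError("expression must be non-empty")
    m = _YEAR_RE.search(raw_expression)
    if m:
        return TimeStamp(kind=TimeKind.ABSOLUTE, value=int(m.group(1)), confidence=1.0)
    m = _AGO_RE.search(raw_expression) or _CJK_AGO_RE.search(raw_expression)
    if m:
        count = _parse_count(m.group(1))
        if count is not None:
            return TimeStamp(
                kind=TimeKind.RELATIVE_RESOLVED,
                value=narration_reference_year - count,
                confidence=0.9,
            )
    return TimeStamp()


def match_anchor(
    event: StructuredEvent,
    db: Sequence[HistoricalEvent],
    embedder: Embedder,
    accept: float = ACCEPT_THRESHOLD,
    flag_low: float = FLAG_THRESHOLD,
) -> tuple[AnchorMatch, TimeStamp] | None:
    """Map an undated event onto the best historical anchor by cosine
    similarity of text features.

    Above ``accept``: unflagged historical timestamp.  In
    ``[flag_low, accept]``: timestamp flagged for human review with
    confidence equal to the similarity.  Below ``flag_low``: no match.
    """
    if flag_low >= accept:
        raise ValueError("flag_low must be below accept")
    if not db:
        return None
    texts = [event.text()] + [f"{h.name}. {h.description}" for h in db]
    vecs = embedder.embed(texts)
    sims = [cosine(vecs[0], vecs[i + 1]) for i in range(len(db))]
    best = int(np.argmax(sims))
    sim = sims[best]
    if sim < flag_low:
        return None
    flagged = sim <= accept
    ts = TimeStamp(
        kind=TimeKind.HISTORICAL_MAPPED,
        value=db[best].year,
        confidence=sim if flagged else 1.0,
        flagged_for_review=flagged,
    )
    return AnchorMatch(event.event_id, db[best], sim), ts


def _narrative_index(
    event: StructuredEvent, segment_index: Mapping[str, int] | None
) -> int:
    if segment_index and event.source_segment_ids:
        return min(
            segment_index.get(sid, 10**9) for sid in event.source_segment_ids
        )
    return 10**9


def build_backbone(
    events: Sequence[StructuredEvent],
    segment_index: Mapping[str, int] | None = None,
) -> Timeline:
    """Sort events with resolvable timestamps chronologically.

    Ties at the same year keep original transcript order (via
    ``segment_index``, a mapping segment_id -> sequence_index; events
    without one keep input order).
    """
    dated = [e for e in events if e.time.year is not None]
    order = sorted(
        range(len(dated)),
        key=lambda i: (dated[i].time.year, _narrative_index(dated[i], segment_index), i),
    )
    return Timeline(
        TimelineEntry(dated[i].event_id, dated[i].time, anchored=True) for i in order
    )


def insert_undated(
    backbone: Timeline,
    undated: Sequence[StructuredEvent],
    rel: CorrelationMatrix,
    alpha: float = 0.5,
    narrative_index: Mapping[str, int] | None = None,
) -> Timeline:
    """Greedily insert undated events into the backbone by relevance.

    Events are processed in transcript order; each is placed at the gap
    maximizing the two-sided relevance score, with relevance to the
    virtual start/end nodes defined as 0.  Insertion immediately extends
    the timeline seen by subsequent events.  ``narrative_index`` maps
    event ids to transcript positions and drives tie-breaking.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    present = set(backbone.event_ids())
    for e in undated:
        if e.event_id in present:
            raise ValidationError(
                f"event {e.event_id!r} is both in the backbone and undated"
            )

    timeline = Timeline(list(backbone))
    idx = {eid: i for i, eid in enumerate(rel.event_ids)}

    def relv(a: str | None, b: str | None) -> float:
        if a is None or b is None:  # virtual node
            return 0.0
        return float(rel.values[idx[a], idx[b]])

    def npos(eid: str) -> int:
        if narrative_index is None:
            return 10**9
        return narrative_index.get(eid, 10**9)

    ordered = sorted(undated, key=lambda e: (npos(e.event_id), e.event_id))
    for ev in ordered:
        ids = timeline.event_ids()
        n = len(ids)
        scores = []
        for gap in range(n + 1):
            left = ids[gap - 1] if gap > 0 else None
            right = ids[gap] if gap < n else None
            scores.append(
                alpha * relv(left, ev.event_id) + (1 - alpha) * relv(ev.event_id, right)
            )
        best = max(scores) if scores else 0.0
        tied = [g for g, s in enumerate(scores) if s == best]
        if len(tied) == 1 or narrative_index is None:
            gap = tied[0]
        else:
            ev_pos = npos(ev.event_id)

            def proximity(g: int) -> tuple:
                flanks = ([ids[g - 1]] if g > 0 else []) + ([ids[g]] if g < n else [])
                dists = [abs(npos(f) - ev_pos) for f in flanks]
                return (min(dists) if dists else 10**9, g)

            gap = min(tied, key=proximity)
        timeline.entries.insert(
            gap,
            TimelineEntry(
                ev.event_id, ev.time, anchored=False, inserted_position_score=best
            ),
        )
    timeline._validate()
    return timeline


def build_timeline(
    events: Sequence[StructuredEvent],
    rel: CorrelationMatrix,
    historical_db: Sequence[HistoricalEvent],
    embedder: Embedder,
    reference_year: int = 2023,
    alpha: float = 0.5,
    segment_index: Mapping[str, int] | None = None,
    exclude_flagged: bool = False,
) -> Timeline:
    """Full timeline pass: normalize raw time expressions, anchor the
    remaining undated events to history, sort the dated backbone, then
    greedily insert whatever is still undated."""
    resolved: list[StructuredEvent] = []
    for ev in events:
        ts = ev.time
        if ts.kind is TimeKind.UNKNOWN and ev.time_expression:
            ts = normalize_time(ev.time_expression, reference_year)
        if ts.kind is TimeKind.UNKNOWN:
            hit = match_anchor(ev, historical_db, embedder) if historical_db else None
            if hit is not None:
                ts = hit[1]
        resolved.append(ev.with_time(ts))

    def datable(e: StructuredEvent) -> bool:
        if e.time.year is None:
            return False
        if exclude_flagged and e.time.flagged_for_review:
            return False
        return True

    dated = [e for e in resolved if datable(e)]
    undated = [e for e in resolved if not datable(e)]
    narrative_index = {
        e.event_id: _narrative_index(e, segment_index) for e in resolved
    }
    backbone = build_backbone(dated, segment_index)
    return insert_undated(backbone, undated, rel, alpha, narrative_index)
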