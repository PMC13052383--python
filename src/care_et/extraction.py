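"""Turn narrative segments into structured events.

Coreference linking over a sliding token window, template-driven element
extraction, maximal-marginal-relevance summary selection, and event
embedding through a pluggable embedder contract.  The neural sentence
encoder of the original system is abstracted behind :class:`Embedder`;
:class:`HashingEmbedder` is the deterministic fallback used for tests and
offline runs.
"""

from __future__ import annotations

import hashlib
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from care_et.event_model import (
    EventFeatureMatrix,
    NarrativeSegment,
    StructuredEvent,
    TimeStamp,
    ValidationError,
)

__all__ = [
    "Embedder",
    "HashingEmbedder",
    "EventTemplate",
    "Mention",
    "MentionLink",
    "tokenize",
    "resolve_coreference",
    "coreference_chains",
    "extract_events",
    "select_summary",
    "embed_events",
    "cosine",
]

_WORD_RE = re.compile(r"[A-Za-z0-9']+")


def _is_cjk(ch: str) -> bool:
    return "CJK" in unicodedata.name(ch, "")


def tokenize(text: str) -> list[str]:
    """Whitespace/word tokenization; each CJK character is its own token."""
    tokens: list[str] = []
    buf = []
    for ch in text:
        if _is_cjk(ch):
            if buf:
                tokens.extend(_WORD_RE.findall("".join(buf)))
                buf = []
            tokens.append(ch)
        else:
            buf.append(ch)
    if buf:
        tokens.extend(_WORD_RE.findall("".join(buf)))
    return tokens


class Embedder(Protocol):
    """Pluggable text-embedding contract.

    Implementations must be deterministic for fixed input and state and
    must return one finite row per input text.
    """

    dimension: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        ...


class HashingEmbedder:
    """Deterministic hashed bag-of-ngrams embedder.

    Token unigrams and character trigrams are hashed (BLAKE2, stable
    across processes) into a fixed-dimension signed feature space; rows
    are L2-normalized.  Texts with no tokens map to a fixed unit vector
    so downstream cosine computations stay defined.
    """

    def __init__(self, dimension: int = 256):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.dimension = dimension

    def _slot(self, feature: str) -> tuple[int, float]:
        h = hashlib.blake2b(feature.encode("utf-8"), digest_size=8).digest()
        idx = int.from_bytes(h[:4], "little") % self.dimension
        sign = 1.0 if h[4] % 2 == 0 else -1.0
        return idx, sign

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dimension), dtype=float)
        for row, text in enumerate(texts):
            tokens = [t.lower() for t in tokenize(text)]
            feats: list[str] = ["w:" + t for t in tokens]
            joined = " ".join(tokens)
            feats += ["c:" + joined[i : i + 3] for i in range(max(0, len(joined) - 2))]
            for f in feats:
                idx, sign = self._slot(f)
                out[row, idx] += sign
            norm = np.linalg.norm(out[row])
            if norm == 0.0:
                out[row, 0] = 1.0
            else:
                out[row] /= norm
        return out


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValidationError("cosine undefined for zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass(frozen=True)
class EventTemplate:
    """A trigger lexicon plus per-role extraction patterns for one event type."""

    event_type: str
    trigger_lexicon: tuple[str, ...]
    element_patterns: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trigger_lexicon:
            raise ValidationError(
                f"template {self.event_type!r}: empty trigger lexicon"
            )


DEFAULT_ELEMENT_PATTERNS: dict[str, tuple[str, ...]] = {
    "time": (
        r"\b(?:1[89]\d{2}|20\d{2})\b",
        r"\b(?:\w+|\d+)\s+years?\s+ago\b",
        r"back then",
    ),
    "location": (r"\bin ([A-Z][a-zA-Z]+(?: [A-Z][a-zA-Z]+)?)\b",),
    "participant": (r"\b(?:with|and) ([A-Z][a-zA-Z]+)\b", r"\bmy (\w+)\b"),
}


@dataclass(frozen=True)
class Mention:
    segment_id: str
    span: tuple[int, int]  # half-open character span
    text: str


@dataclass(frozen=True)
class MentionLink:
    mention_a: Mention
    mention_b: Mention
    similarity: float


def _default_mentions(segments: Sequence[NarrativeSegment]) -> list[Mention]:
    """Candidate mentions: capitalized tokens and possessive-kin phrases."""
    mentions = []
    pat = re.compile(r"\b(?:[A-Z][a-z]+|my \w+)\b")
    for seg in segments:
        for m in pat.finditer(seg.text):
            if m.start() == 0 and not m.group().startswith("my"):
                continue  # skip sentence-initial capitals
            mentions.append(Mention(seg.segment_id, (m.start(), m.end()), m.group()))
    return mentions


def resolve_coreference(
    segments: Sequence[NarrativeSegment],
    embedder: Embedder,
    window_tokens: int = 512,
    threshold: float = 0.8,
    mentions: Sequence[Mention] | None = None,
) -> list[MentionLink]:
    """Link coreferent mentions by embedding cosine similarity.

    Mentions are compared only when their token positions fall within one
    sliding window of ``window_tokens`` over the concatenated session
    stream; a link is accepted when cosine similarity of the mention
    surface embeddings reaches ``threshold``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if window_tokens < 1:
        raise ValueError("window_tokens must be >= 1")
    if not segments:
        return []
    if mentions is None:
        mentions = _default_mentions(segments)
    if not mentions:
        return []

    # token offset of each segment inside its session stream
    seg_by_id = {s.segment_id: s for s in segments}
    offsets: dict[str, int] = {}
    session_cursor: dict[str, int] = {}
    for seg in sorted(segments, key=lambda s: (s.session_id, s.sequence_index)):
        cur = session_cursor.get(seg.session_id, 0)
        offsets[seg.segment_id] = cur
        session_cursor[seg.session_id] = cur + len(tokenize(seg.text))

    def token_pos(m: Mention) -> int:
        seg = seg_by_id[m.segment_id]
        return offsets[m.segment_id] + len(tokenize(seg.text[: m.span[0]]))

    vecs = embedder.embed([m.text for m in mentions])
    positions = [token_pos(m) for m in mentions]
    sessions = [seg_by_id[m.segment_id].session_id for m in mentions]

    links: list[MentionLink] = []
    for i in range(len(mentions)):
        for j in range(i + 1, len(mentions)):
            if sessions[i] != sessions[j]:
                continue
            if abs(positions[i] - positions[j]) >= window_tokens:
                continue
            sim = cosine(vecs[i], vecs[j])
            if sim >= threshold:
                links.append(MentionLink(mentions[i], mentions[j], sim))
    return links


def coreference_chains(links: Sequence[MentionLink]) -> list[list[Mention]]:
    """Partition linked mentions into chains by transitive closure.

    Each chain is sorted by (segment_id, span); the first element is the
    chain representative (earliest mention).
    """
    parent: dict[Mention, Mention] = {}

    def find(x: Mention) -> Mention:
        while parent[x] is not x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for link in links:
        for m in (link.mention_a, link.mention_b):
            parent.setdefault(m, m)
        ra, rb = find(link.mention_a), find(link.mention_b)
        if ra is not rb:
            parent[rb] = ra

    groups: dict[Mention, list[Mention]] = {}
    for m in parent:
        groups.setdefault(find(m), []).append(m)
    chains = [sorted(g, key=lambda m: (m.segment_id, m.span)) for g in groups.values()]
    chains.sort(key=lambda c: (c[0].segment_id, c[0].span))
    return chains


def _first_match(text: str, patterns: Sequence[str]) -> str | None:
    for pat in patterns:
        m = re.search(pat, text)
        if m:
            return m.group(1) if m.groups() else m.group(0)
    return None


def extract_events(
    segments: Sequence[NarrativeSegment],
    templates: Sequence[EventTemplate],
    links: Sequence[MentionLink] = (),
) -> list[StructuredEvent]:
    """Extract one structured event per matched trigger occurrence.

    Trigger matching is case-insensitive whole-token matching against each
    template's lexicon.  Participants are canonicalized to their
    coreference-chain representative (earliest mention).  Time is left as
    kind=unknown with the raw expression recorded for later normalization.
    When several templates share a trigger, every match is reported.
    """
    if not templates:
        raise ValueError("templates must be non-empty")

    canon: dict[str, str] = {}
    for chain in coreference_chains(links):
        rep = chain[0].text
        for m in chain:
            canon[m.text.lower()] = rep

    events: list[StructuredEvent] = []
    counter = 0
    for seg in sorted(segments, key=lambda s: (s.session_id, s.sequence_index)):
        for tmpl in templates:
            for trig in tmpl.trigger_lexicon:
                for m in re.finditer(
                    r"(?<!\w)" + re.escape(trig) + r"(?!\w)", seg.text, re.IGNORECASE
                ):
                    patterns = {**DEFAULT_ELEMENT_PATTERNS, **dict(tmpl.element_patterns)}
                    raw_time = _first_match(seg.text, patterns.get("time", ()))
                    location = _first_match(seg.text, patterns.get("location", ()))
                    participant = _first_match(seg.text, patterns.get("participant", ()))
                    participants = []
                    if participant:
                        participants.append(
                            canon.get(participant.lower(), participant)
                        )
                    events.append(
                        StructuredEvent(
                            event_id=f"ev-{counter:06d}",
                            event_type=tmpl.event_type,
                            trigger=m.group(0),
                            time=TimeStamp(),
                            location=location,
                            participants=participants,
                            summary=[seg.text.strip()][:1],
                            source_segment_ids=[seg.segment_id],
                            time_expression=raw_time,
                        )
                    )
                    counter += 1
    return events


def select_summary(
    event: StructuredEvent,
    candidate_sentences: Sequence[str],
    salience: Sequence[float],
    k: int = 3,
    diversity_weight: float = 0.7,
    embedder: Embedder | None = None,
) -> list[str]:
    """Greedy maximal-marginal-relevance selection of up to ``k`` sentences.

    The first pick is the argmax of ``salience``; each subsequent pick
    maximizes ``diversity_weight * salience - (1 - diversity_weight) *
    max-cosine-to-picked``.  Returns sentences in pick order.
    """
    if len(candidate_sentences) != len(salience):
        raise ValueError("salience length must match candidates")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not candidate_sentences:
        return []
    if embedder is None:
        embedder = HashingEmbedder()
    vecs = embedder.embed(list(candidate_sentences))
    sal = np.asarray(salience, dtype=float)

    picked: list[int] = [int(np.argmax(sal))]
    while len(picked) < min(k, len(candidate_sentences)):
        best_idx, best_score = None, -np.inf
        for i in range(len(candidate_sentences)):
            if i in picked:
                continue
            redundancy = max(cosine(vecs[i], vecs[p]) for p in picked)
            score = diversity_weight * sal[i] - (1 - diversity_weight) * redundancy
            if score > best_score:
                best_idx, best_score = i, score
        picked.append(best_idx)
    return [candidate_sentences[i] for i in picked]


def tfidf_salience(sentences: Sequence[str]) -> list[float]:
    """Centroid salience: cosine of each sentence to the corpus centroid
    of hashed features.  Shipped default scorer for summary selection."""
    if not sentences:
        return []
    vecs = HashingEmbedder().embed(list(sentences))
    centroid = vecs.mean(axis=0)
    if np.linalg.norm(centroid) == 0.0:
        return [0.0] * len(sentences)
    return [cosine(v, centroid) for v in vecs]


def embed_events(
    events: Sequence[StructuredEvent], embedder: Embedder
) -> EventFeatureMatrix:
    """Embed each event's concatenated surface form into the feature matrix."""
    if not events:
        raise ValueError("events must be non-empty")
    texts = [e.text() for e in events]
    matrix = embedder.embed(texts)
    if matrix.shape != (len(events), embedder.dimension):
        raise ValidationError(
            f"embedder returned shape {matrix.shape}, expected "
            f"({len(events)}, {embedder.dimension})"
        )
    return EventFeatureMatrix([e.event_id for e in events], matrix)
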