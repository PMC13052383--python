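"""Generate fragmented life-story corpora with known ground truth.

The generator emulates the structural properties of fragmented oral
histories — near-duplicate retellings, mixed absolute/relative/historical
time expressions, fully undated events, shuffled narration order — while
returning the true chronological order and cluster labels so every
pipeline stage is testable without external data.  Fractions are applied
by quota sampling so tests can assert exact counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from care_et.event_model import (
    EventFeatureMatrix,
    HistoricalEvent,
    NarrativeSegment,
    TimeKind,
    TimeStamp,
    Timeline,
    TimelineEntry,
)

__all__ = ["SimConfig", "StoryCorpus", "generate_story", "generate_clustered_features",
           "FIXTURE_HISTORICAL_DB"]

# small anchor table of the same shape as the real 1900-2000 database
FIXTURE_HISTORICAL_DB: list[HistoricalEvent] = [
    HistoricalEvent("Great Flood", 1931, "the great river flood displaced villages"),
    HistoricalEvent("Liberation War", 1949, "the liberation war ended and the new state was founded"),
    HistoricalEvent("Land Reform", 1952, "the land reform redistributed farmland"),
    HistoricalEvent("Great Famine", 1960, "the great famine years of scarce grain"),
    HistoricalEvent("Moon Landing", 1969, "astronauts first landed on the moon"),
    HistoricalEvent("Reform Opening", 1978, "the reform and opening of the economy began"),
    HistoricalEvent("Asian Games", 1990, "the asian games were hosted in the capital"),
    HistoricalEvent("Handover", 1997, "the territory handover ceremony"),
    HistoricalEvent("Millennium", 2000, "the millennium celebrations"),
]

# theme -> (trigger, location, participant) token pools; themes double as
# ground-truth clusters
_THEMES: list[tuple[str, list[str], list[str], list[str]]] = [
    ("family", ["married", "celebrated", "welcomed"],
     ["Nanjing", "Wuhu"], ["Mei", "my wife", "my son"]),
    ("career", ["worked", "promoted", "retired"],
     ["Shanghai", "Hefei"], ["my foreman", "my apprentice"]),
    ("school", ["studied", "graduated", "enrolled"],
     ["Beijing", "Chuzhou"], ["my teacher", "my classmate"]),
    ("travel", ["traveled", "moved", "visited"],
     ["Guilin", "Chengdu"], ["my brother", "my cousin"]),
]

_PARAPHRASE = {
    "married": "wed", "celebrated": "feasted", "welcomed": "embraced",
    "worked": "labored", "promoted": "advanced", "retired": "stepped down",
    "studied": "learned", "graduated": "finished school", "enrolled": "signed up",
    "traveled": "journeyed", "moved": "relocated", "visited": "called on",
}


@dataclass
class SimConfig:
    n_events: int = 20
    undated_fraction: float = 0.0
    redundancy_rate: float = 0.0
    relative_time_fraction: float = 0.0
    historical_fraction: float = 0.0
    n_clusters: int = 4
    cluster_separation: float = 5.0
    shuffle: bool = True
    seed: int = 0
    reference_year: int = 2023

    def __post_init__(self) -> None:
        for name in ("undated_fraction", "redundancy_rate",
                     "relative_time_fraction", "historical_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.undated_fraction + self.relative_time_fraction + self.historical_fraction > 1.0 + 1e-9:
            raise ValueError("time-mode fractions must sum to at most 1")
        if self.n_events < self.n_clusters:
            raise ValueError("n_events must be >= n_clusters")


@dataclass
class StoryCorpus:
    segments: list[NarrativeSegment]
    truth_timeline: Timeline
    truth_clusters: dict[str, int]
    historical_db: list[HistoricalEvent]
    truth_years: dict[str, int] = field(default_factory=dict)
    segment_of_event: dict[str, list[str]] = field(default_factory=dict)
    # timestamp as narrated in the text (unknown for undated events)
    narrated_time: dict[str, TimeStamp] = field(default_factory=dict)


def _quota_indices(rng: np.random.Generator, n: int, fractions: list[float]) -> list[np.ndarray]:
    """Disjoint index sets of exact sizes round(f*n), drawn without
    replacement in one pass."""
    counts = [int(round(f * n)) for f in fractions]
    perm = rng.permutation(n)
    out, cur = [], 0
    for c in counts:
        out.append(np.sort(perm[cur : cur + c]))
        cur += c
    return out


def generate_story(config: SimConfig) -> StoryCorpus:
    """Draw a life course of events, render each to narrative text, apply
    time-expression modes and redundancy, and optionally shuffle.

    Chronological order is the event draw order (years strictly
    increasing), so the ground-truth timeline is exact.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events

    years = np.sort(
        rng.choice(np.arange(1945, 1945 + max(n * 3, 60)), size=n, replace=False)
    )
    themes = [i % config.n_clusters for i in range(n)]
    rng.shuffle(themes)

    undated_idx, relative_idx, historical_idx = _quota_indices(
        rng,
        n,
        [config.undated_fraction, config.relative_time_fraction, config.historical_fraction],
    )
    undated_set, relative_set, historical_set = (
        set(undated_idx.tolist()), set(relative_idx.tolist()), set(historical_idx.tolist()),
    )

    segments: list[NarrativeSegment] = []
    entries: list[TimelineEntry] = []
    clusters: dict[str, int] = {}
    truth_years: dict[str, int] = {}
    segment_of_event: dict[str, list[str]] = {}

    def render(i: int, trigger: str) -> str:
        theme_id = themes[i]
        _, _, locs, parts = _THEMES[theme_id % len(_THEMES)]
        loc = locs[int(rng.integers(len(locs)))]
        part = parts[int(rng.integers(len(parts)))]
        year = int(years[i])
        if i in undated_set:
            time_phrase = "back then"
        elif i in relative_set:
            time_phrase = f"{config.reference_year - year} years ago"
        elif i in historical_set:
            anchor = min(FIXTURE_HISTORICAL_DB, key=lambda h: abs(h.year - year))
            time_phrase = f"around the {anchor.name}, {anchor.description},"
        else:
            time_phrase = f"in {year}"
        return f"I {trigger} with {part} {time_phrase} in {loc}."

    seg_counter = 0
    for i in range(n):
        eid = f"ev-{i:06d}"
        theme_id = themes[i]
        theme_name, triggers, _, _ = _THEMES[theme_id % len(_THEMES)]
        trigger = triggers[int(rng.integers(len(triggers)))]
        text = render(i, trigger)
        sid = f"seg-{seg_counter:06d}"
        seg_counter += 1
        segments.append(
            NarrativeSegment(segment_id=sid, session_id="session-0",
                             sequence_index=0, text=text)
        )
        segment_of_event[eid] = [sid]
        if rng.random() < config.redundancy_rate:
            para = text.replace(trigger, _PARAPHRASE.get(trigger, trigger))
            sid2 = f"seg-{seg_counter:06d}"
            seg_counter += 1
            segments.append(
                NarrativeSegment(segment_id=sid2, session_id="session-0",
                                 sequence_index=0, text=para)
            )
            segment_of_event[eid].append(sid2)
        year = int(years[i])
        truth_years[eid] = year
        clusters[eid] = theme_id
        if i in undated_set:
            ts = TimeStamp()
            anchored = False
        elif i in historical_set:
            anchor = min(FIXTURE_HISTORICAL_DB, key=lambda h: abs(h.year - year))
            ts = TimeStamp(kind=TimeKind.HISTORICAL_MAPPED, value=anchor.year,
                           confidence=1.0)
            anchored = True
        elif i in relative_set:
            ts = TimeStamp(kind=TimeKind.RELATIVE_RESOLVED, value=year, confidence=0.9)
            anchored = True
        else:
            ts = TimeStamp(kind=TimeKind.ABSOLUTE, value=year)
            anchored = True
        entries.append(TimelineEntry(eid, ts, anchored=anchored))

    # the true timeline is chronological by the *true* years regardless of
    # how (or whether) the rendered text dates each event
    order = sorted(range(n), key=lambda i: years[i])
    truth = Timeline(
        TimelineEntry(
            entries[i].event_id,
            TimeStamp(kind=TimeKind.ABSOLUTE, value=int(years[i])),
            anchored=True,
        )
        for i in order
    )

    if config.shuffle:
        perm = rng.permutation(len(segments))
        segments = [segments[int(p)] for p in perm]
    segments = [
        NarrativeSegment(s.segment_id, s.session_id, idx, s.text)
        for idx, s in enumerate(segments)
    ]

    return StoryCorpus(
        segments=segments,
        truth_timeline=truth,
        truth_clusters=clusters,
        historical_db=list(FIXTURE_HISTORICAL_DB),
        truth_years=truth_years,
        segment_of_event=segment_of_event,
        narrated_time={e.event_id: e.time for e in entries},
    )


def generate_clustered_features(
    n: int, k: int, separation: float, dim: int = 8, seed: int = 0
) -> tuple[EventFeatureMatrix, np.ndarray]:
    """k isotropic unit-variance Gaussian blobs with centroids
    ``separation`` apart along orthogonal axes; returns features and
    planted labels."""
    if n < k:
        raise ValueError("n must be >= k")
    rng = np.random.default_rng(seed)
    centroids = np.zeros((k, dim))
    for c in range(k):
        centroids[c, c % dim] = separation
    labels = np.array([i % k for i in range(n)])
    rng.shuffle(labels)
    X = centroids[labels] + rng.normal(0, 1.0, size=(n, dim))
    # guard the no-all-zero-row invariant (vanishing probability, but exact)
    X[np.all(X == 0.0, axis=1), 0] = 1e-9
    ids = [f"ev-{i:06d}" for i in range(n)]
    return EventFeatureMatrix(ids, X), labels
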