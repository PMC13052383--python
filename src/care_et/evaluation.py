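"""Storyline and timeline quality metrics.

Two storyline-link (SLEU) formulations are implemented under distinct
names — the h-gram matching form (geometric mean of subsequence match
probabilities) and the positional-decay form — because the two printed
definitions are incompatible; reports must state which was used.
Timeline fidelity is measured by absolute rank deviation and Kendall
tau-a order preservation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, exp, log
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import kendalltau

from care_et.event_model import Timeline

__all__ = [
    "StorylinePair",
    "count_hgrams",
    "sleu_hgram",
    "sleu_positional",
    "timid_absolute",
    "timid_relative",
    "relative_reduction",
    "rouge_scores",
    "exact_match_similarity",
]


@dataclass
class StorylinePair:
    """A system storyline, a reference storyline, and the sentence
    similarity function used to decide h-gram matches."""

    predicted: Sequence[str]
    reference: Sequence[str]
    sentence_similarity: Callable[[str, str], float]

    def __post_init__(self) -> None:
        if not self.predicted or not self.reference:
            raise ValueError("storylines must be non-empty")


def exact_match_similarity(a: str, b: str) -> float:
    return 1.0 if a == b else 0.0


def count_hgrams(n: int, h: int) -> int:
    """Number of h-element subsequences (not necessarily consecutive) of
    an n-element storyline: C(n, h)."""
    if h < 1 or h > n:
        raise ValueError(f"require 1 <= h <= n, got h={h}, n={n}")
    return comb(n, h)


def _match_count(
    source: Sequence[str],
    target: Sequence[str],
    h: int,
    sim: Callable[[str, str], float],
    threshold: float,
) -> int:
    """Greedy count of source h-grams matched to distinct target h-grams.

    Two h-grams match when every position-aligned sentence pair exceeds
    the similarity threshold; each target h-gram is used at most once.
    """
    src = list(combinations(range(len(source)), h))
    tgt = list(combinations(range(len(target)), h))
    used = [False] * len(tgt)
    matched = 0
    for s in src:
        for ti, t in enumerate(tgt):
            if used[ti]:
                continue
            if all(sim(source[i], target[j]) > threshold for i, j in zip(s, t)):
                used[ti] = True
                matched += 1
                break
    return matched


def sleu_hgram(
    pair: StorylinePair,
    match_threshold: float = 0.2,
    weights: Mapping[int, float] | None = None,
) -> float:
    """h-gram SLEU: exp(sum_h w_h log p_h) with
    p_h = min(matched predicted, matched reference) / C(n, h).

    Any p_h of zero yields a score of zero.
    """
    n = len(pair.reference)
    if weights is None:
        hs = [h for h in (1, 2) if h <= min(n, len(pair.predicted))]
        weights = {h: 1.0 / len(hs) for h in hs}
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError("h-gram weights must sum to 1")
    acc = 0.0
    for h, w in weights.items():
        denom = count_hgrams(n, h)
        m_pred = _match_count(
            pair.predicted, pair.reference, h, pair.sentence_similarity, match_threshold
        )
        m_ref = _match_count(
            pair.reference, pair.predicted, h, pair.sentence_similarity, match_threshold
        )
        p_h = min(m_pred, m_ref) / denom
        if p_h == 0.0:
            return 0.0
        acc += w * log(p_h)
    return exp(acc)


def sleu_positional(
    pred_positions: Mapping[str, int],
    ref_positions: Mapping[str, int],
    H: int = 3,
    decay: float = 0.5,
) -> float:
    """Positional-decay SLEU.

    With mean absolute rank deviation d over the shared events, the score
    is sum_{h=1..H} (1/h) * exp(-decay * d), normalized by sum(1/h) so an
    identical ordering scores exactly 1.
    """
    if set(pred_positions) != set(ref_positions):
        raise ValueError("position maps must cover the same events")
    devs = [abs(pred_positions[e] - ref_positions[e]) for e in pred_positions]
    mean_dev = float(np.mean(devs))
    w = [1.0 / h for h in range(1, H + 1)]
    return sum(wh * exp(-decay * mean_dev) for wh in w) / sum(w)


def _ranks(timeline: Timeline | Sequence[str]) -> dict[str, int]:
    ids = timeline.event_ids() if isinstance(timeline, Timeline) else list(timeline)
    return {eid: i + 1 for i, eid in enumerate(ids)}  # 1-based ranks


def timid_absolute(
    pred: Timeline | Sequence[str],
    ref: Timeline | Sequence[str],
    normalized: bool = False,
) -> float:
    """Mean absolute rank deviation between two orderings of the same
    events.  Raw rank units by default; ``normalized`` divides ranks by N."""
    rp, rr = _ranks(pred), _ranks(ref)
    if set(rp) != set(rr):
        raise ValueError("timelines must contain the same events")
    N = len(rp)
    scale = N if normalized else 1
    return float(np.mean([abs(rp[e] - rr[e]) / scale for e in rp]))


def timid_relative(
    pred: Timeline | Sequence[str], ref: Timeline | Sequence[str]
) -> float:
    """Kendall tau-a rank correlation between the two event orders."""
    rp, rr = _ranks(pred), _ranks(ref)
    if set(rp) != set(rr):
        raise ValueError("timelines must contain the same events")
    events = sorted(rp)
    if len(events) < 2:
        return 1.0
    tau = kendalltau([rp[e] for e in events], [rr[e] for e in events]).statistic
    return float(tau)


def relative_reduction(baseline_mean: float, treated_mean: float) -> float:
    """100 * (baseline - treated) / baseline, to one decimal place."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return round(100.0 * (baseline_mean - treated_mean) / baseline_mean, 1)


# ---------------------------------------------------------------------------
# summary-overlap metrics


def _ngrams(tokens: Sequence[str], n: int) -> dict[tuple, int]:
    counts: dict[tuple, int] = {}
    for i in range(len(tokens) - n + 1):
        g = tuple(tokens[i : i + n])
        counts[g] = counts.get(g, 0) + 1
    return counts


def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    dp = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            dp[i][j] = (
                dp[i - 1][j - 1] + 1
                if a[i - 1] == b[j - 1]
                else max(dp[i - 1][j], dp[i][j - 1])
            )
    return dp[-1][-1]


def _f1(overlap: int, pred_n: int, ref_n: int) -> float:
    if pred_n == 0 or ref_n == 0 or overlap == 0:
        return 0.0
    p, r = overlap / pred_n, overlap / ref_n
    return 2 * p * r / (p + r)


def rouge_scores(predicted: str, reference: str) -> dict[str, float]:
    """Unigram/bigram/longest-common-subsequence overlap F1 (lowercased
    whitespace tokens).  Checked against a hand-computed fixture in the
    test suite."""
    pt = predicted.lower().split()
    rt = reference.lower().split()
    out: dict[str, float] = {}
    for n, name in ((1, "rouge1"), (2, "rouge2")):
        pc, rc = _ngrams(pt, n), _ngrams(rt, n)
        overlap = sum(min(c, rc.get(g, 0)) for g, c in pc.items())
        out[name] = _f1(overlap, max(len(pt) - n + 1, 0), max(len(rt) - n + 1, 0))
    out["rougeL"] = _f1(_lcs_len(pt, rt), len(pt), len(rt))
    return out
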