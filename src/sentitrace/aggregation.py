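"""Aggregate scored posts into the surveillance outputs.

Four views: overall class proportions, weekly cross-platform sentiment
series, county-level spatial summaries, and sentiment-conditional term
frequencies (word-cloud tables).

Weekly binning uses ISO-8601 weeks on UTC calendar dates.  The
cross-platform "weighted" average is post-count weighting, i.e. pooling:
a week's mean score is the grand mean over every post in that week,
whichever platform it came from.  Equal-platform weighting is available
by flag for sensitivity analysis.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .lexicon import tokenize
from .models import CLASS_ORDER, Platform, ScoredPost, SentimentLabel

try:
    from shapely.geometry import Point, shape
except ImportError:  # pragma: no cover - shapely is a hard dependency
    Point = shape = None

__all__ = [
    "WeeklyPoint",
    "RegionSummary",
    "TermFrequencyTable",
    "overall_proportions",
    "weekly_series",
    "region_summaries",
    "rank_regions",
    "term_frequencies",
    "load_region_boundaries",
    "DEFAULT_STOPWORDS",
]

logger = logging.getLogger(__name__)

POS, NEU, NEG = CLASS_ORDER


def _label_props(labels: Sequence[SentimentLabel]) -> tuple[float, float, float]:
    n = len(labels)
    return tuple(sum(l is c for l in labels) / n for c in CLASS_ORDER)


def overall_proportions(
    scored: Sequence[ScoredPost],
) -> dict[SentimentLabel, float]:
    """Proportions of final labels over the corpus; sums to 1."""
    if not scored:
        raise ValueError("cannot compute proportions of an empty corpus")
    props = _label_props([sp.final_label for sp in scored])
    return dict(zip(CLASS_ORDER, props))


@dataclass(frozen=True)
class WeeklyPoint:
    """One ISO week of combined cross-platform sentiment.

    ``mean_score`` is the post-count-weighted (pooled) mean of the
    ensemble score over both platforms; NaN when the week is empty
    (``n_a + n_b == 0``), in which case ``empty`` is set.
    """

    iso_year: int
    iso_week: int
    n_a: int
    n_b: int
    mean_score: float
    prop_positive: float
    prop_neutral: float
    prop_negative: float

    @property
    def n(self) -> int:
        return self.n_a + self.n_b

    @property
    def empty(self) -> bool:
        return self.n == 0


def weekly_series(
    scored: Sequence[ScoredPost],
    equal_platform_weights: bool = False,
) -> list[WeeklyPoint]:
    """One point per ISO week from the first to the last populated week.

    Weeks inside the span with zero posts are emitted with ``n == 0`` and
    NaN mean (flagged, never fabricated).  With
    ``equal_platform_weights`` the week mean averages the two per-platform
    means instead of pooling.
    """
    if not scored:
        return []
    by_week: dict[tuple[int, int], list[ScoredPost]] = {}
    for sp in scored:
        iso = sp.post.timestamp.date().isocalendar()
        by_week.setdefault((iso.year, iso.week), []).append(sp)

    weeks = sorted(by_week)
    # Enumerate every ISO week between the first and last populated one.
    import datetime as _dt

    first = _dt.date.fromisocalendar(*weeks[0], 1)
    last = _dt.date.fromisocalendar(*weeks[-1], 1)
    span: list[tuple[int, int]] = []
    d = first
    while d <= last:
        iso = d.isocalendar()
        span.append((iso.year, iso.week))
        d += _dt.timedelta(days=7)

    out: list[WeeklyPoint] = []
    for year, week in span:
        group = by_week.get((year, week), [])
        n_a = sum(sp.post.platform is Platform.PLATFORM_A for sp in group)
        n_b = len(group) - n_a
        if not group:
            out.append(WeeklyPoint(year, week, 0, 0, float("nan"), 0.0, 0.0, 0.0))
            continue
        if equal_platform_weights:
            means = [
                float(np.mean([sp.lexicon_ensemble_score for sp in group
                               if sp.post.platform is plat]))
                for plat in Platform
                if any(sp.post.platform is plat for sp in group)
            ]
            mean = float(np.mean(means))
        else:
            mean = float(np.mean([sp.lexicon_ensemble_score for sp in group]))
        p_pos, p_neu, p_neg = _label_props([sp.final_label for sp in group])
        out.append(WeeklyPoint(year, week, n_a, n_b, mean, p_pos, p_neu, p_neg))
    return out


@dataclass(frozen=True)
class RegionSummary:
    """Aggregated sentiment for one region (county)."""

    region_id: str
    n_posts: int
    mean_score: float
    prop_positive: float
    prop_negative: float


def load_region_boundaries(path) -> dict[str, object]:
    """Load region polygons from a GeoJSON FeatureCollection.

    Each feature must carry a ``region_id`` (or ``id``) property; returns
    a map region_id -> shapely geometry for point-in-polygon assignment.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    out: dict[str, object] = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        rid = props.get("region_id") or props.get("id") or feat.get("id")
        if rid is None:
            raise ValueError("GeoJSON feature lacks a region_id property")
        out[str(rid)] = shape(feat["geometry"])
    return out


def region_summaries(
    scored: Sequence[ScoredPost],
    region_ids: Optional[Sequence[str]] = None,
    boundaries: Optional[Mapping[str, object]] = None,
) -> tuple[list[RegionSummary], int]:
    """Per-region sentiment summaries over geo-resolvable posts.

    A post resolves by its direct region code when present, else by
    point-in-polygon of its coordinates against ``boundaries``.  Posts
    with no geographic metadata, or with coordinates outside every
    polygon, are unresolvable; they are counted (second return value) and
    logged, never silently dropped.  Regions declared in ``region_ids``
    with no posts appear with ``n_posts == 0`` and NaN mean (flagged, not
    fabricated).
    """
    by_region: dict[str, list[ScoredPost]] = {
        str(r): [] for r in (region_ids or [])
    }
    n_unresolved = 0
    for sp in scored:
        rid = sp.post.region
        if rid is None and sp.post.latitude is not None and boundaries:
            pt = Point(sp.post.longitude, sp.post.latitude)
            rid = next(
                (r for r, geom in boundaries.items() if geom.contains(pt)), None
            )
        if rid is None:
            n_unresolved += 1
            continue
        by_region.setdefault(str(rid), []).append(sp)
    if n_unresolved:
        logger.info("region summaries: %d post(s) not geo-resolvable", n_unresolved)

    out: list[RegionSummary] = []
    for rid in sorted(by_region):
        group = by_region[rid]
        if not group:
            out.append(RegionSummary(rid, 0, float("nan"), 0.0, 0.0))
            continue
        p_pos, _, p_neg = _label_props([sp.final_label for sp in group])
        mean = float(np.mean([sp.lexicon_ensemble_score for sp in group]))
        out.append(RegionSummary(rid, len(group), mean, p_pos, p_neg))
    return out, n_unresolved


def rank_regions(
    summaries: Sequence[RegionSummary],
    k: int = 5,
    most: str = "positive",
    min_n: int = 5,
) -> list[RegionSummary]:
    """Top-k regions by mean score (most positive or most negative).

    Regions with fewer than ``min_n`` posts are excluded from rankings so
    single-post counties cannot dominate; they remain in the summaries.
    """
    if most not in ("positive", "negative"):
        raise ValueError(f"most must be 'positive' or 'negative', got {most!r}")
    eligible = [s for s in summaries if s.n_posts >= min_n]
    sign = -1.0 if most == "positive" else 1.0
    return sorted(eligible, key=lambda s: (sign * s.mean_score, s.region_id))[:k]


#: Minimal English stopword list for term-frequency tables.
DEFAULT_STOPWORDS = frozenset(
    """a about after again all also am an and any are as at be because been
    before being but by can could did do does doing down during each few for
    from further had has have having he her here hers him his how i if in
    into is it its itself just me more most my myself of off on once only or
    other our ours out over own s said same she should so some such t than
    that the their theirs them then there these they this those through to
    too under until up ve very was we were what when where which while who
    whom why will with you your yours""".split()
)


@dataclass(frozen=True)
class TermFrequencyTable:
    """Ranked (term, count) list for one sentiment stratum — the data
    behind a sentiment word cloud."""

    stratum: str
    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.entries]
        if any(c <= 0 for c in counts):
            raise ValueError("term counts must be positive")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("entries must be ranked by non-increasing count")


def term_frequencies(
    scored: Sequence[ScoredPost],
    label: Optional[SentimentLabel] = None,
    window: Optional[tuple] = None,
    stopwords: frozenset = DEFAULT_STOPWORDS,
    exclude_terms: Sequence[str] = (),
    top_k: Optional[int] = None,
) -> TermFrequencyTable:
    """Term counts over a sentiment stratum.

    ``label`` restricts to posts with that final label; ``window`` is an
    optional (start_date, end_date) UTC date pair.  Configured stopwords
    and the corpus filter keywords themselves (``exclude_terms``) are
    removed — the filter keywords appear in essentially every post by
    construction and would dominate every cloud.  Ranking is stable:
    count descending, then lexicographic.
    """
    excluded = set(stopwords) | {
        tok for phrase in exclude_terms for tok in tokenize(phrase)
    }
    counts: dict[str, int] = {}
    for sp in scored:
        if label is not None and sp.final_label is not label:
            continue
        if window is not None:
            d = sp.post.timestamp.date()
            if not (window[0] <= d <= window[1]):
                continue
        for tok in tokenize(sp.post.text):
            if tok in excluded or len(tok) < 2:
                continue
            counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ranked = ranked[:top_k]
    stratum = label.value if label is not None else "all"
    return TermFrequencyTable(stratum, tuple(ranked))
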