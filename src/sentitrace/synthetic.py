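"""Synthetic two-platform post corpus with known ground truth.

The generator emulates the shape of the study corpus so every pipeline
stage is testable without any download: two platforms at an 80/20 split
(8000 + 2000 posts in the default profile), a March 1 – October 31 2020
window, 76/12/12 positive/neutral-negative class proportions, UK county
region labels on the geo-tagged fraction, and class-conditional vocabulary
drawn from the same packaged valence lexicon the scorer tests use.

Every post's text is composed of class-conditional valence terms plus one
pandemic keyword and one app keyword (so the corpus survives the two-step
thematic filter) plus neutral noise terms.  A ``separability`` knob sets
the fraction of class-informative terms per post, making both easy and
hard regimes testable.  All randomness flows through one seeded NumPy
generator; identical spec + seed reproduces the corpus byte for byte.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .filtering import APP_KEYWORDS, DEFAULT_COVID_KEYWORDS
from .lexicon import ValenceLexicon, load_fixture_lexicon
from .models import CLASS_ORDER, Platform, Post, SentimentLabel

__all__ = [
    "VocabPools",
    "GeneratorSpec",
    "generate_corpus",
    "generate_labelled_validation",
    "step_schedule",
    "iso_weeks_in_span",
    "default_vocab",
    "load_uk_counties",
]

POS, NEU, NEG = CLASS_ORDER

#: Mundane, valence-free filler vocabulary.  Deliberately disjoint from the
#: packaged lexicon's three tables and from every filter-keyword token.
NOISE_TERMS = (
    "android", "area", "battery", "bluetooth", "bus", "city", "code",
    "council", "country", "data", "december", "device", "download",
    "email", "england", "evening", "family", "government", "iphone",
    "link", "local", "message", "million", "minister", "mobile", "month",
    "morning", "national", "neighbour", "news", "notification", "number",
    "october", "office", "percent", "phone", "public", "report", "school",
    "scotland", "service", "shop", "status", "store", "street", "system",
    "today", "tomorrow", "town", "train", "update", "version", "wales",
    "website", "week", "yesterday",
)


@dataclass(frozen=True)
class VocabPools:
    """Class-conditional term pools for text composition.

    ``positive`` / ``negative`` carry strong valence terms; ``neutral``
    and ``noise`` are valence-free filler; ``covid_keywords`` and
    ``app_keywords`` are the planted thematic-filter anchors.  The three
    class pools must be pairwise disjoint.
    """

    positive: tuple[str, ...]
    negative: tuple[str, ...]
    neutral: tuple[str, ...]
    noise: tuple[str, ...]
    covid_keywords: tuple[str, ...] = DEFAULT_COVID_KEYWORDS
    app_keywords: tuple[str, ...] = APP_KEYWORDS

    def __post_init__(self) -> None:
        pools = {
            "positive": set(self.positive),
            "negative": set(self.negative),
            "neutral": set(self.neutral) | set(self.noise),
        }
        names = list(pools)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = pools[a] & pools[b]
                if overlap:
                    raise ValueError(
                        f"vocab pools {a!r} and {b!r} overlap: {sorted(overlap)[:5]}"
                    )
        for name in ("positive", "negative", "covid_keywords", "app_keywords"):
            if not getattr(self, name):
                raise ValueError(f"vocab pool {name!r} is empty")

    def pool_for(self, label: SentimentLabel) -> tuple[str, ...]:
        if label is POS:
            return self.positive
        if label is NEG:
            return self.negative
        return self.neutral


def default_vocab(
    lexicon: Optional[ValenceLexicon] = None,
    min_valence: float = 1.8,
) -> VocabPools:
    """Pools derived from the packaged lexicon: terms with |valence| >=
    ``min_valence`` become the class pools, mundane filler the rest."""
    lex = lexicon if lexicon is not None else load_fixture_lexicon()
    pos = tuple(sorted(t for t, v in lex.entries.items() if v >= min_valence))
    neg = tuple(sorted(t for t, v in lex.entries.items() if v <= -min_valence))
    half = len(NOISE_TERMS) // 2
    return VocabPools(pos, neg, NOISE_TERMS[:half], NOISE_TERMS[half:])


def load_uk_counties() -> dict[str, str]:
    """Packaged UK county lookup: region_id -> display name."""
    ref = resources.files("sentitrace.data") / "uk_counties.tsv"
    lines = ref.read_text(encoding="utf-8").strip().splitlines()[1:]
    return dict(line.split("\t", 1) for line in lines)


def iso_weeks_in_span(
    start: dt.date, end: dt.date
) -> list[tuple[tuple[int, int], int]]:
    """ISO weeks intersecting [start, end], with in-span day counts."""
    if start > end:
        raise ValueError("start must be <= end")
    out: list[tuple[tuple[int, int], int]] = []
    d = start
    while d <= end:
        iso = d.isocalendar()
        key = (iso.year, iso.week)
        if out and out[-1][0] == key:
            out[-1] = (key, out[-1][1] + 1)
        else:
            out.append((key, 1))
        d += dt.timedelta(days=1)
    return out


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything that determines a synthetic corpus.

    The defaults are the study-shaped profile: 10,000 posts split 80/20
    across the two platforms, 76/12/12 positive/neutral/negative gold
    proportions over the March 1 – October 31 2020 window, half the posts
    geo-tagged with UK county labels.  ``weekly_trend`` optionally
    overrides the class proportions per ISO week, e.g. a step change at a
    named event week.
    """

    n_posts: int = 10_000
    platform_split: float = 0.8  # fraction on platform A
    class_proportions: tuple[float, float, float] = (0.76, 0.12, 0.12)
    start_date: dt.date = dt.date(2020, 3, 1)
    end_date: dt.date = dt.date(2020, 10, 31)
    weekly_trend: Optional[Mapping[tuple[int, int], tuple[float, float, float]]] = None
    region_distribution: Optional[Mapping[str, float]] = None
    geo_fraction: float = 0.5
    separability: float = 0.9
    terms_per_post: tuple[int, int] = (3, 8)
    language: str = "en"
    vocab: VocabPools = field(default_factory=default_vocab)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_posts <= 0:
            raise ValueError("n_posts must be positive")
        if not 0.0 <= self.platform_split <= 1.0:
            raise ValueError("platform_split must be in [0, 1]")
        for name, props in [("class_proportions", self.class_proportions)] + (
            [(f"weekly_trend[{k}]", v) for k, v in (self.weekly_trend or {}).items()]
        ):
            if len(props) != 3 or any(p < 0 for p in props):
                raise ValueError(f"{name} must be 3 non-negative reals")
            if abs(sum(props) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1, got {sum(props)}")
        if self.region_distribution is not None:
            total = sum(self.region_distribution.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"region_distribution must sum to 1, got {total}")
        if not 0.0 <= self.geo_fraction <= 1.0:
            raise ValueError("geo_fraction must be in [0, 1]")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must be in [0, 1]")
        lo, hi = self.terms_per_post
        if lo < 1 or hi < lo:
            raise ValueError("terms_per_post must be (lo, hi) with 1 <= lo <= hi")
        if self.start_date > self.end_date:
            raise ValueError("start_date must be <= end_date")

    def with_(self, **changes) -> "GeneratorSpec":
        return replace(self, **changes)


def step_schedule(
    spec_or_start,
    end: Optional[dt.date] = None,
    step_week: tuple[int, int] = (2020, 20),
    before: tuple[float, float, float] = (0.80, 0.10, 0.10),
    after: tuple[float, float, float] = (0.60, 0.10, 0.30),
) -> dict[tuple[int, int], tuple[float, float, float]]:
    """A weekly-trend schedule with one step change at ``step_week``:
    proportions are ``before`` up to the week preceding it and ``after``
    from that ISO week on."""
    if isinstance(spec_or_start, GeneratorSpec):
        start, end = spec_or_start.start_date, spec_or_start.end_date
    else:
        start = spec_or_start
        if end is None:
            raise ValueError("end date required")
    sched: dict[tuple[int, int], tuple[float, float, float]] = {}
    for (year, week), _ in iso_weeks_in_span(start, end):
        sched[(year, week)] = after if (year, week) >= step_week else before
    return sched


def _compose_text(
    rng: np.random.Generator,
    label: SentimentLabel,
    vocab: VocabPools,
    separability: float,
    terms_per_post: tuple[int, int],
) -> str:
    n_terms = int(rng.integers(terms_per_post[0], terms_per_post[1] + 1))
    class_pool = vocab.pool_for(label)
    words: list[str] = []
    for _ in range(n_terms):
        informative = rng.random() < separability
        pool = class_pool if informative else vocab.noise
        words.append(pool[int(rng.integers(len(pool)))])
    # Plant the thematic anchors the two-step filter requires.
    words.append(vocab.covid_keywords[int(rng.integers(len(vocab.covid_keywords)))])
    words.append(vocab.app_keywords[int(rng.integers(len(vocab.app_keywords)))])
    order = rng.permutation(len(words))
    return " ".join(words[i] for i in order)


def generate_corpus(spec: GeneratorSpec) -> list[Post]:
    """Generate exactly ``spec.n_posts`` gold-labelled posts.

    Each post: gold class drawn from the (possibly week-dependent)
    proportions; text composed per :func:`_compose_text`; timestamp
    uniform over the assigned ISO week's in-window days; platform and
    region drawn independently.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    weeks = iso_weeks_in_span(spec.start_date, spec.end_date)
    week_keys = [k for k, _ in weeks]
    week_days = np.array([n for _, n in weeks], dtype=float)
    week_probs = week_days / week_days.sum()

    if spec.region_distribution is not None:
        regions = sorted(spec.region_distribution)
        region_probs = np.array([spec.region_distribution[r] for r in regions])
    else:
        regions = sorted(load_uk_counties())
        region_probs = np.full(len(regions), 1.0 / len(regions))

    class_labels = list(CLASS_ORDER)
    posts: list[Post] = []
    for i in range(spec.n_posts):
        wk_idx = int(rng.choice(len(week_keys), p=week_probs))
        (year, week), n_days = weeks[wk_idx]
        props = spec.class_proportions
        if spec.weekly_trend is not None:
            props = spec.weekly_trend.get((year, week), props)
        label = class_labels[int(rng.choice(3, p=np.asarray(props, dtype=float)))]

        # Uniform timestamp over the week's in-window days.
        week_monday = dt.date.fromisocalendar(year, week, 1)
        in_span = [
            week_monday + dt.timedelta(days=d)
            for d in range(7)
            if spec.start_date <= week_monday + dt.timedelta(days=d) <= spec.end_date
        ]
        day = in_span[int(rng.integers(len(in_span)))]
        seconds = int(rng.integers(86_400))
        ts = dt.datetime.combine(day, dt.time()) + dt.timedelta(seconds=seconds)
        ts = ts.replace(tzinfo=dt.timezone.utc)

        platform = (
            Platform.PLATFORM_A
            if rng.random() < spec.platform_split
            else Platform.PLATFORM_B
        )
        region = None
        if rng.random() < spec.geo_fraction:
            region = regions[int(rng.choice(len(regions), p=region_probs))]

        text = _compose_text(
            rng, label, spec.vocab, spec.separability, spec.terms_per_post
        )
        posts.append(
            Post(
                post_id=f"syn-{i:06d}",
                platform=platform,
                timestamp=ts,
                text=text,
                region=region,
                language=spec.language,
                gold_label=label,
            )
        )
    return posts


def generate_labelled_validation(
    spec: GeneratorSpec,
    n_labelled: int,
    corpus: Optional[Sequence[Post]] = None,
) -> list[Post]:
    """Uniform random subsample without replacement of a generated corpus,
    emulating a manually labelled validation set.  Seed-deterministic; the
    subsample draw is independent of the corpus draw so the same spec
    yields the same subset of the same corpus."""
    if corpus is None:
        corpus = generate_corpus(spec)
    if n_labelled > len(corpus):
        raise ValueError(
            f"n_labelled={n_labelled} exceeds corpus size {len(corpus)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5AB5]))
    idx = rng.choice(len(corpus), size=n_labelled, replace=False)
    return [corpus[int(i)] for i in sorted(idx)]
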