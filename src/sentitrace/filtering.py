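"""Thematic and window filters that define the analysis corpus.

The corpus is built by a two-step thematic filter — a broad pandemic
keyword pass followed by a contact-tracing-app keyword pass — and a
window filter on date, declared language and region scope.  All filters
are order-preserving subsequence selectors.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

from .models import Post

__all__ = [
    "KeywordFilterSpec",
    "CorpusWindow",
    "APP_KEYWORDS",
    "DEFAULT_COVID_KEYWORDS",
    "default_app_spec",
    "default_covid_spec",
    "apply_keyword_filter",
    "two_step_filter",
    "apply_window",
]

logger = logging.getLogger(__name__)

#: Second-step filter: the 11 contact-tracing-app keyword phrases.
APP_KEYWORDS = (
    "covid app",
    "tracing app",
    "contact tracing",
    "privacy",
    "security",
    "app security",
    "app privacy",
    "contain virus spread",
    "movement tracking",
    "tracking",
    "surveillance",
)

#: First-step pandemic keywords. The upstream chatter datasets apply their
#: own predefined lists; this default is a configurable stand-in.
DEFAULT_COVID_KEYWORDS = (
    "covid",
    "covid19",
    "covid-19",
    "coronavirus",
    "sars-cov-2",
    "pandemic",
    "lockdown",
)


@dataclass(frozen=True)
class KeywordFilterSpec:
    """A named keyword filter.

    ``match_mode`` is ``token_phrase`` (phrases must match whole tokens
    after lower-casing and punctuation stripping, so ``tracking`` matches
    ``"tracking!"`` but not ``"backtracking"``) or ``substring``.
    """

    name: str
    keywords: tuple[str, ...]
    match_mode: str = "token_phrase"

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"filter {self.name!r}: keywords must be non-empty")
        if self.match_mode not in ("token_phrase", "substring"):
            raise ValueError(f"filter {self.name!r}: unknown match_mode {self.match_mode!r}")
        folded = tuple(k.strip().lower() for k in self.keywords)
        if any(not k for k in folded):
            raise ValueError(f"filter {self.name!r}: empty keyword phrase")
        if len(set(folded)) != len(folded):
            dupes = sorted({k for k in folded if folded.count(k) > 1})
            raise ValueError(f"filter {self.name!r}: duplicate keyword(s) {dupes}")
        object.__setattr__(self, "keywords", folded)

    def _compiled(self) -> re.Pattern:
        parts = []
        for phrase in self.keywords:
            esc = r"[\s\W]+".join(re.escape(tok) for tok in phrase.split())
            if self.match_mode == "token_phrase":
                esc = rf"(?<!\w){esc}(?!\w)"
            parts.append(esc)
        return re.compile("|".join(parts))

    def matches(self, text: str) -> bool:
        return self._pattern.search(text.lower()) is not None

    @property
    def _pattern(self) -> re.Pattern:
        pat = getattr(self, "_pat_cache", None)
        if pat is None:
            pat = self._compiled()
            object.__setattr__(self, "_pat_cache", pat)
        return pat

    def with_keywords(self, extra: Sequence[str]) -> "KeywordFilterSpec":
        return KeywordFilterSpec(self.name, self.keywords + tuple(extra), self.match_mode)


def default_app_spec(match_mode: str = "token_phrase") -> KeywordFilterSpec:
    """The packaged second-step contact-tracing-app filter."""
    return KeywordFilterSpec("app_keywords", APP_KEYWORDS, match_mode)


def default_covid_spec(match_mode: str = "token_phrase") -> KeywordFilterSpec:
    """The configurable first-step pandemic filter."""
    return KeywordFilterSpec("covid_keywords", DEFAULT_COVID_KEYWORDS, match_mode)


@dataclass(frozen=True)
class CorpusWindow:
    """Date span (inclusive both ends, UTC calendar dates), language and
    region scope that define the analysis window."""

    start_date: date
    end_date: date
    language: Optional[str] = "en"
    region_scope: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("start_date must be <= end_date")
        if self.region_scope is not None:
            object.__setattr__(self, "region_scope", frozenset(self.region_scope))


def apply_keyword_filter(
    posts: Sequence[Post], spec: KeywordFilterSpec
) -> list[Post]:
    """Retain exactly the posts whose case-folded text matches >=1 keyword.

    Order preserved; idempotent; empty result is valid.
    """
    kept = [p for p in posts if spec.matches(p.text)]
    logger.info(
        "keyword filter %s: retained %d / %d posts", spec.name, len(kept), len(posts)
    )
    return kept


def two_step_filter(
    posts: Sequence[Post],
    covid_spec: KeywordFilterSpec,
    app_spec: KeywordFilterSpec,
) -> list[Post]:
    """Pandemic-keyword pass first, then the app-keyword pass."""
    return apply_keyword_filter(apply_keyword_filter(posts, covid_spec), app_spec)


def apply_window(posts: Sequence[Post], window: CorpusWindow) -> list[Post]:
    """Retain posts inside the date window, language and region scope.

    Posts lacking a declared language are flagged through with a warning
    (language identification is out of scope); posts lacking any region
    metadata pass the window filter — they are excluded later, at spatial
    aggregation, not here.
    """
    kept: list[Post] = []
    n_unknown_lang = 0
    for p in posts:
        d = p.timestamp.date()
        if not (window.start_date <= d <= window.end_date):
            continue
        if window.language is not None:
            if p.language is None:
                n_unknown_lang += 1
            elif p.language.lower() != window.language.lower():
                continue
        if window.region_scope is not None and p.region is not None:
            if p.region not in window.region_scope:
                continue
        kept.append(p)
    if n_unknown_lang:
        logger.warning(
            "window filter: %d post(s) lack a declared language; retained",
            n_unknown_lang,
        )
    logger.info("window filter: retained %d / %d posts", len(kept), len(posts))
    return kept
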