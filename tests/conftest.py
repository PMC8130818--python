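"""Shared fixtures: the packaged lexicon, default vocab pools, a default
registry/ensemble, and factories for posts and scored posts."""

from __future__ import annotations

import datetime as dt
import itertools

import pytest

from sentitrace.ensemble import EnsembleConfig, KeywordTableClassifier
from sentitrace.lexicon import default_registry, load_fixture_lexicon
from sentitrace.models import Platform, Post, ScoredPost, SentimentLabel
from sentitrace.synthetic import default_vocab

_counter = itertools.count()


@pytest.fixture(scope="session")
def lexicon():
    return load_fixture_lexicon()


@pytest.fixture(scope="session")
def vocab(lexicon):
    return default_vocab(lexicon)


@pytest.fixture(scope="session")
def registry(lexicon):
    return default_registry(lexicon)


@pytest.fixture()
def ensemble_config(vocab):
    return EnsembleConfig(
        contextual=KeywordTableClassifier(vocab.positive, vocab.negative)
    )


@pytest.fixture(scope="session")
def make_post():
    """Factory for valid posts with auto-unique ids and sane defaults."""

    def _make(
        text: str = "covid tracing app news",
        *,
        post_id: str | None = None,
        platform: Platform = Platform.PLATFORM_A,
        timestamp: dt.datetime | None = None,
        **kwargs,
    ) -> Post:
        return Post(
            post_id=post_id or f"p{next(_counter):05d}",
            platform=platform,
            timestamp=timestamp
            or dt.datetime(2020, 6, 15, 12, 0, tzinfo=dt.timezone.utc),
            text=text,
            **kwargs,
        )

    return _make


@pytest.fixture(scope="session")
def make_scored(make_post):
    """Factory for scored posts; the final label defaults to the sign of
    the ensemble score at +/-0.05 thresholds."""

    def _make(score: float = 0.5, *, final_label=None, **post_kwargs) -> ScoredPost:
        if final_label is None:
            if score >= 0.05:
                final_label = SentimentLabel.POSITIVE
            elif score <= -0.05:
                final_label = SentimentLabel.NEGATIVE
            else:
                final_label = SentimentLabel.NEUTRAL
        return ScoredPost(
            post=make_post(**post_kwargs),
            lexicon_a_score=score,
            lexicon_b_score=score,
            lexicon_ensemble_score=score,
            lexicon_label=final_label,
            contextual_label=final_label,
            final_label=final_label,
        )

    return _make
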