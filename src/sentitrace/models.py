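"""Core record types for the sentiment-surveillance pipeline.

A :class:`Post` is the unit of everything downstream: one social-media
record with a platform role, a UTC timestamp, free text, and optional
geography and gold sentiment label.  A :class:`ScoredPost` carries a post
through the full ensemble: two continuous lexicon polarity scores, their
weighted combination, the label that combination maps to, the contextual
classifier's label, and the fused final label.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Optional

__all__ = [
    "SentimentLabel",
    "Platform",
    "Post",
    "ScoredPost",
    "CLASS_ORDER",
    "validate_polarity",
]


class SentimentLabel(str, enum.Enum):
    """Three-class categorical sentiment. No total order is assumed."""

    POSITIVE = "positive"
    NEUTRAL = "neutral"
    NEGATIVE = "negative"

    @classmethod
    def parse(cls, value: str) -> "SentimentLabel":
        try:
            return cls(value.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown sentiment label {value!r}; "
                f"expected one of {[m.value for m in cls]}"
            ) from None


#: Fixed class order for confusion matrices and proportion triples.
CLASS_ORDER = (
    SentimentLabel.POSITIVE,
    SentimentLabel.NEUTRAL,
    SentimentLabel.NEGATIVE,
)


class Platform(str, enum.Enum):
    """Two-platform roles (the study's Facebook- and Twitter-like sources)."""

    PLATFORM_A = "platform_a"
    PLATFORM_B = "platform_b"

    @classmethod
    def parse(cls, value: str) -> "Platform":
        try:
            return cls(value.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown platform {value!r}; expected one of "
                f"{[m.value for m in cls]} (map raw platform names first)"
            ) from None


def validate_polarity(value: float, what: str = "polarity score") -> float:
    """Check a continuous polarity value lies in [-1, 1] and is finite."""
    value = float(value)
    if not math.isfinite(value) or not -1.0 <= value <= 1.0:
        raise ValueError(f"{what} must be a finite real in [-1, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class Post:
    """One social-media record.

    Parameters
    ----------
    post_id
        Opaque identifier, unique within a corpus.
    platform
        One of the two platform roles.
    timestamp
        Timezone-resolved instant; stored in UTC.  Naive datetimes are
        rejected: weekly binning must be unambiguous.
    text
        Free text; must be non-empty after whitespace normalisation.
    region
        Optional region code (UK county level in the default profile).
    latitude, longitude
        Optional WGS84 decimal degrees; must be given together.
    language
        Optional declared language code (e.g. ``"en"``).
    gold_label
        Optional human-assigned sentiment label.
    """

    post_id: str
    platform: Platform
    timestamp: datetime
    text: str
    region: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    language: Optional[str] = None
    gold_label: Optional[SentimentLabel] = None

    def __post_init__(self) -> None:
        if not self.post_id:
            raise ValueError("post_id must be non-empty")
        if not isinstance(self.platform, Platform):
            object.__setattr__(self, "platform", Platform.parse(str(self.platform)))
        ts = self.timestamp
        if not isinstance(ts, datetime):
            raise ValueError(f"timestamp must be a datetime, got {type(ts).__name__}")
        if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
            raise ValueError(
                f"post {self.post_id}: timestamp lacks a timezone; "
                "timezone-naive timestamps are rejected"
            )
        object.__setattr__(self, "timestamp", ts.astimezone(timezone.utc))
        if not self.text or not self.text.strip():
            raise ValueError(f"post {self.post_id}: text is empty")
        if (self.latitude is None) != (self.longitude is None):
            raise ValueError(
                f"post {self.post_id}: latitude and longitude must be given together"
            )
        if self.latitude is not None:
            if not -90.0 <= float(self.latitude) <= 90.0:
                raise ValueError(f"post {self.post_id}: latitude out of range")
            if not -180.0 <= float(self.longitude) <= 180.0:
                raise ValueError(f"post {self.post_id}: longitude out of range")
        if self.gold_label is not None and not isinstance(
            self.gold_label, SentimentLabel
        ):
            object.__setattr__(
                self, "gold_label", SentimentLabel.parse(str(self.gold_label))
            )

    @property
    def has_geo(self) -> bool:
        """True when the post can enter spatial aggregation."""
        return self.region is not None or self.latitude is not None

    def with_(self, **changes) -> "Post":
        return replace(self, **changes)


@dataclass(frozen=True)
class ScoredPost:
    """A post with all channel outputs of the hybrid ensemble attached."""

    post: Post
    lexicon_a_score: float
    lexicon_b_score: float
    lexicon_ensemble_score: float
    lexicon_label: SentimentLabel
    contextual_label: SentimentLabel
    final_label: SentimentLabel

    def __post_init__(self) -> None:
        validate_polarity(self.lexicon_a_score, "lexicon_a_score")
        validate_polarity(self.lexicon_b_score, "lexicon_b_score")
        validate_polarity(self.lexicon_ensemble_score, "lexicon_ensemble_score")
        for name in ("lexicon_label", "contextual_label", "final_label"):
            val = getattr(self, name)
            if not isinstance(val, SentimentLabel):
                object.__setattr__(self, name, SentimentLabel.parse(str(val)))
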