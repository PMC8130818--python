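"""Read and write post corpora as delimited (CSV) or JSON-lines text.

Validation is total: every input row is either accepted or produces a
diagnostic carrying its line number; nothing is silently dropped.  A file
with any malformed row raises :class:`CorpusValidationError` listing every
problem found, so a single pass reports all defects.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .models import Platform, Post, ScoredPost, SentimentLabel

__all__ = [
    "RowError",
    "CorpusValidationError",
    "read_posts",
    "write_posts",
    "read_scored",
    "write_scored",
]

POST_COLUMNS = (
    "post_id",
    "platform",
    "timestamp",
    "text",
    "region",
    "latitude",
    "longitude",
    "language",
    "gold_label",
)
REQUIRED_COLUMNS = ("post_id", "platform", "timestamp", "text")
SCORE_COLUMNS = (
    "lexicon_a_score",
    "lexicon_b_score",
    "lexicon_ensemble_score",
    "lexicon_label",
    "contextual_label",
    "final_label",
)


@dataclass(frozen=True)
class RowError:
    """A located diagnostic for one malformed input row."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"line {self.line}: {self.message}"


class CorpusValidationError(ValueError):
    """Raised when any row of an input file fails validation."""

    def __init__(self, path, errors: Sequence[RowError]):
        self.path = str(path)
        self.errors = list(errors)
        head = "; ".join(str(e) for e in self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{self.path}: {len(self.errors)} invalid row(s): {head}{more}")


def _parse_timestamp(raw: str) -> datetime:
    # ISO-8601; 'Z' suffix accepted. Naive timestamps are rejected by Post.
    ts = datetime.fromisoformat(raw.strip().replace("Z", "+00:00"))
    return ts


def _row_to_post(
    row: Mapping[str, object],
    platform_map: Optional[Mapping[str, str]],
) -> Post:
    def opt(key):
        val = row.get(key)
        if val is None:
            return None
        val = str(val).strip()
        return val or None

    raw_platform = str(row["platform"]).strip().lower()
    if platform_map:
        raw_platform = platform_map.get(raw_platform, raw_platform)
    lat, lon = opt("latitude"), opt("longitude")
    gold = opt("gold_label")
    return Post(
        post_id=str(row["post_id"]).strip(),
        platform=Platform.parse(raw_platform),
        timestamp=_parse_timestamp(str(row["timestamp"])),
        text=str(row["text"]),
        region=opt("region"),
        latitude=float(lat) if lat is not None else None,
        longitude=float(lon) if lon is not None else None,
        language=opt("language"),
        gold_label=SentimentLabel.parse(gold) if gold is not None else None,
    )


def _validate_rows(
    rows: Iterable[tuple[int, Mapping[str, object]]],
    path,
    platform_map: Optional[Mapping[str, str]],
) -> list[Post]:
    posts: list[Post] = []
    errors: list[RowError] = []
    seen_ids: dict[str, int] = {}
    for line, row in rows:
        try:
            post = _row_to_post(row, platform_map)
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(RowError(line, str(exc)))
            continue
        if post.post_id in seen_ids:
            errors.append(
                RowError(
                    line,
                    f"duplicate post_id {post.post_id!r} "
                    f"(first seen on line {seen_ids[post.post_id]})",
                )
            )
            continue
        seen_ids[post.post_id] = line
        posts.append(post)
    if errors:
        raise CorpusValidationError(path, errors)
    return posts


def read_posts(
    path,
    fmt: str = "csv",
    column_map: Optional[Mapping[str, str]] = None,
    platform_map: Optional[Mapping[str, str]] = None,
) -> list[Post]:
    """Read a post corpus from a delimited or JSON-lines file.

    Parameters
    ----------
    path
        File to read; UTF-8 mandatory.
    fmt
        ``"csv"`` (header row required) or ``"jsonl"`` (one object per line).
    column_map
        Optional map from file column names to canonical field names.
    platform_map
        Optional map from raw platform strings (e.g. ``"facebook"``) to the
        two-role enum values ``platform_a`` / ``platform_b``.

    Returns
    -------
    list of Post, in file order.

    Raises
    ------
    ValueError
        If a required column is missing (named in the message).
    CorpusValidationError
        If any row fails validation; carries per-row line numbers.
    """
    path = Path(path)
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            if column_map:
                header = [column_map.get(c, c) for c in header]
            for col in REQUIRED_COLUMNS:
                if col not in header:
                    raise ValueError(f"{path}: missing required column {col!r}")
            rows = (
                (i, dict(zip(header, [row.get(c) for c in (reader.fieldnames or [])])))
                for i, row in enumerate(reader, start=2)
            )
            return _validate_rows(rows, path, platform_map)
    elif fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            parsed: list[tuple[int, Mapping[str, object]]] = []
            errors: list[RowError] = []
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    errors.append(RowError(i, f"invalid JSON: {exc}"))
                    continue
                if column_map:
                    obj = {column_map.get(k, k): v for k, v in obj.items()}
                missing = [c for c in REQUIRED_COLUMNS if c not in obj]
                if missing:
                    errors.append(RowError(i, f"missing required field(s) {missing}"))
                    continue
                parsed.append((i, obj))
            if errors:
                raise CorpusValidationError(path, errors)
            return _validate_rows(parsed, path, platform_map)
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'jsonl'")


def _post_to_row(post: Post) -> dict:
    return {
        "post_id": post.post_id,
        "platform": post.platform.value,
        "timestamp": post.timestamp.isoformat(),
        "text": post.text,
        "region": post.region or "",
        "latitude": "" if post.latitude is None else repr(float(post.latitude)),
        "longitude": "" if post.longitude is None else repr(float(post.longitude)),
        "language": post.language or "",
        "gold_label": post.gold_label.value if post.gold_label else "",
    }


def write_posts(posts: Sequence[Post], path, fmt: str = "csv") -> None:
    """Write posts so that :func:`read_posts` round-trips them losslessly."""
    path = Path(path)
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=POST_COLUMNS, lineterminator="\n")
            writer.writeheader()
            for post in posts:
                writer.writerow(_post_to_row(post))
    elif fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for post in posts:
                row = {k: v for k, v in _post_to_row(post).items() if v != ""}
                for key in ("latitude", "longitude"):
                    if key in row:
                        row[key] = float(row[key])
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'jsonl'")


def write_scored(scored: Sequence[ScoredPost], path) -> None:
    """Write scored posts as CSV; scores at full (repr) precision."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=POST_COLUMNS + SCORE_COLUMNS, lineterminator="\n"
        )
        writer.writeheader()
        for sp in scored:
            row = _post_to_row(sp.post)
            row.update(
                lexicon_a_score=repr(float(sp.lexicon_a_score)),
                lexicon_b_score=repr(float(sp.lexicon_b_score)),
                lexicon_ensemble_score=repr(float(sp.lexicon_ensemble_score)),
                lexicon_label=sp.lexicon_label.value,
                contextual_label=sp.contextual_label.value,
                final_label=sp.final_label.value,
            )
            writer.writerow(row)


def read_scored(path) -> list[ScoredPost]:
    """Read a scored-post file written by :func:`write_scored`."""
    path = Path(path)
    scored: list[ScoredPost] = []
    errors: list[RowError] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in REQUIRED_COLUMNS + SCORE_COLUMNS:
            if col not in (reader.fieldnames or []):
                raise ValueError(f"{path}: missing required column {col!r}")
        for i, row in enumerate(reader, start=2):
            try:
                post = _row_to_post(row, None)
                scored.append(
                    ScoredPost(
                        post=post,
                        lexicon_a_score=float(row["lexicon_a_score"]),
                        lexicon_b_score=float(row["lexicon_b_score"]),
                        lexicon_ensemble_score=float(row["lexicon_ensemble_score"]),
                        lexicon_label=SentimentLabel.parse(row["lexicon_label"]),
                        contextual_label=SentimentLabel.parse(row["contextual_label"]),
                        final_label=SentimentLabel.parse(row["final_label"]),
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                errors.append(RowError(i, str(exc)))
    if errors:
        raise CorpusValidationError(path, errors)
    return scored
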