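"""Self-contained lexicon rule-based polarity scoring.

Two continuous-polarity channels share one valence dictionary and one
grammatical rule walk:

* ``lexicon_a`` — saturating-sum scorer: token valences are summed after
  negation and booster adjustments and the raw sum ``s`` is normalised to
  ``s / sqrt(s**2 + alpha)``, an odd sigmoid onto (-1, 1).
* ``lexicon_b`` — averaging scorer: the mean adjusted valence of matched
  tokens is rescaled from the dictionary scale [-4, 4] onto [-1, 1].

The sum channel saturates with accumulating evidence (long rants score
near +/-1); the averaging channel is length-invariant.  Fusing the two is
what the ensemble's weighted average is for.

External scorers plug in through :class:`ScorerContract` and a
:class:`ScorerRegistry`; registration runs a probe battery and refuses any
scorer that leaves [-1, 1].
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

__all__ = [
    "ValenceLexicon",
    "ScorerParams",
    "tokenize",
    "score_text",
    "average_score_text",
    "normalize_raw_sum",
    "ScorerContract",
    "ScorerRegistry",
    "default_registry",
    "load_fixture_lexicon",
]

logger = logging.getLogger(__name__)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[\w']+")

#: Dictionary valence scale; scores are normalised from this onto [-1, 1].
LEXICON_SCALE = 4.0


def tokenize(
    text: str,
    strip_urls: bool = True,
    strip_mentions: bool = True,
    split_hashtags: bool = True,
    lowercase: bool = True,
) -> list[str]:
    """Split a post into word tokens.

    URLs and @-mentions are stripped and hashtags are split off their
    marker (``#trustit`` -> ``trustit``) by default; apostrophes stay
    inside tokens so contracted negators (``don't``) survive.
    """
    if strip_urls:
        text = _URL_RE.sub(" ", text)
    if strip_mentions:
        text = _MENTION_RE.sub(" ", text)
    if split_hashtags:
        text = text.replace("#", " ")
    if lowercase:
        text = text.lower()
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class ValenceLexicon:
    """Valence dictionary with booster and negator tables.

    ``entries`` maps lowercase terms to valences in [-4, 4]; ``boosters``
    maps intensifiers to increments applied toward a following valence
    token's sign; ``negators`` flip-and-dampen a following valence token.
    Terms must be lowercase and unique across the three tables.
    """

    entries: Mapping[str, float]
    boosters: Mapping[str, float] = field(default_factory=dict)
    negators: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "boosters", dict(self.boosters))
        object.__setattr__(self, "negators", frozenset(self.negators))
        tables = [
            ("entries", self.entries.keys()),
            ("boosters", self.boosters.keys()),
            ("negators", self.negators),
        ]
        seen: dict[str, str] = {}
        for table, terms in tables:
            for term in terms:
                if term != term.lower():
                    raise ValueError(f"{table}: term {term!r} is not lowercase")
                if term in seen:
                    raise ValueError(
                        f"term {term!r} appears in both {seen[term]} and {table}"
                    )
                seen[term] = table
        for term, val in list(self.entries.items()) + list(self.boosters.items()):
            if not math.isfinite(float(val)):
                raise ValueError(f"non-finite valence for {term!r}")

    def mirrored(self) -> "ValenceLexicon":
        """The lexicon with every valence negated (for symmetry checks)."""
        return ValenceLexicon(
            {t: -v for t, v in self.entries.items()}, self.boosters, self.negators
        )

    @classmethod
    def load(cls, path) -> "ValenceLexicon":
        """Load from 2-column delimited text with optional ``#BOOSTERS`` /
        ``#NEGATORS`` sections (tab- or whitespace-separated)."""
        entries: dict[str, float] = {}
        boosters: dict[str, float] = {}
        negators: set[str] = set()
        section = "entries"
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.upper().startswith("#BOOSTERS"):
                section = "boosters"
                continue
            if line.upper().startswith("#NEGATORS"):
                section = "negators"
                continue
            if line.startswith("#"):
                continue
            if section == "negators":
                negators.add(line.split()[0].lower())
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"lexicon line needs term and valence: {raw!r}")
            term, val = parts[0].lower(), float(parts[1])
            (entries if section == "entries" else boosters)[term] = val
        return cls(entries, boosters, negators)


def load_fixture_lexicon() -> ValenceLexicon:
    """The ~300-term lexicon packaged for tests and simulation."""
    ref = resources.files("sentitrace.data") / "fixture_lexicon.txt"
    with resources.as_file(ref) as path:
        return ValenceLexicon.load(path)


@dataclass(frozen=True)
class ScorerParams:
    """Grammatical-rule and normalisation parameters.

    alpha
        Normalisation constant in ``s / sqrt(s**2 + alpha)``; 15 is the
        convention in the valence-lexicon literature this scorer follows.
    negation_window
        A negator within this many preceding tokens flips a valence token.
    negation_factor
        Multiplier applied on negation; -0.74 flips the sign and dampens
        the magnitude ("not good" is weaker criticism than "bad").
    emphasis
        Optional all-caps / exclamation amplification, off by default to
        keep the scorer minimal and auditable.
    """

    alpha: float = 15.0
    negation_window: int = 3
    negation_factor: float = -0.74
    emphasis: bool = False
    caps_increment: float = 0.733
    exclaim_increment: float = 0.292
    max_exclaims: int = 3

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.negation_window < 1:
            raise ValueError("negation_window must be >= 1")


DEFAULT_PARAMS = ScorerParams()


def normalize_raw_sum(s: float, alpha: float = 15.0) -> float:
    """Map an unbounded valence sum onto (-1, 1); exactly 0 stays 0."""
    return s / math.sqrt(s * s + alpha)


def _adjusted_valences(
    text: str, lexicon: ValenceLexicon, params: ScorerParams
) -> list[float]:
    """The rule walk: per matched token, its valence after booster and
    negation adjustments, in token order."""
    raw_tokens = tokenize(text, lowercase=False)
    tokens = [t.lower() for t in raw_tokens]
    hits: list[float] = []
    for i, tok in enumerate(tokens):
        v = lexicon.entries.get(tok)
        if v is None:
            continue
        if params.emphasis and raw_tokens[i].isupper() and len(raw_tokens[i]) > 1:
            v += math.copysign(params.caps_increment, v)
        if i > 0:
            inc = lexicon.boosters.get(tokens[i - 1])
            if inc is not None:
                v += math.copysign(inc, v)
        lo = max(0, i - params.negation_window)
        if any(t in lexicon.negators for t in tokens[lo:i]):
            v *= params.negation_factor
        hits.append(v)
    return hits


def score_text(
    text: str,
    lexicon: ValenceLexicon,
    params: ScorerParams = DEFAULT_PARAMS,
) -> float:
    """Saturating-sum polarity of a whole post, in [-1, 1].

    Tokenises the post, sums adjusted token valences and normalises the
    raw sum ``s`` to ``s / sqrt(s**2 + alpha)``.  Texts with no dictionary
    hits score exactly 0.
    """
    if not text or not text.strip():
        logger.warning("scoring empty text; returning 0")
        return 0.0
    hits = _adjusted_valences(text, lexicon, params)
    if not hits:
        return 0.0
    s = sum(hits)
    if params.emphasis:
        n_ex = min(text.count("!"), params.max_exclaims)
        s += math.copysign(n_ex * params.exclaim_increment, s) if s else 0.0
    return normalize_raw_sum(s, params.alpha)


def average_score_text(
    text: str,
    lexicon: ValenceLexicon,
    params: ScorerParams = DEFAULT_PARAMS,
) -> float:
    """Length-invariant averaging polarity: mean adjusted valence of
    matched tokens rescaled from [-4, 4] onto [-1, 1]; 0 with no hits."""
    if not text or not text.strip():
        logger.warning("scoring empty text; returning 0")
        return 0.0
    hits = _adjusted_valences(text, lexicon, params)
    if not hits:
        return 0.0
    mean = sum(hits) / len(hits)
    return max(-1.0, min(1.0, mean / LEXICON_SCALE))


@dataclass(frozen=True)
class ScorerContract:
    """A pluggable continuous-polarity channel: ``score(text)`` must return
    a value in [-1, 1]; ``deterministic`` promises same text -> same score."""

    name: str
    score: Callable[[str], float]
    deterministic: bool = True


#: Probe battery run at registration; any score outside [-1, 1] refuses the
#: contract.  Deliberately adversarial: empty, emoji, long repetition.
PROBE_TEXTS = (
    "",
    "   ",
    "good",
    "bad",
    "not good",
    "very very good news " * 50,
    "terrible awful horrible " * 50,
    "\U0001f600 \U0001f621 café naïve 你好",
    "no sentiment words here at all",
    "!!!???",
)


class ScorerRegistry:
    """Named registry of polarity channels selectable by the ensemble."""

    def __init__(self) -> None:
        self._scorers: dict[str, ScorerContract] = {}

    def register(self, contract: ScorerContract) -> str:
        """Register a scorer after it passes the probe battery.

        Returns the channel handle (the contract's name).  Registration is
        refused if the name is taken or any probe score leaves [-1, 1].
        """
        if contract.name in self._scorers:
            raise ValueError(f"scorer {contract.name!r} is already registered")
        # Probes include degenerate texts on purpose; silence the scorer's
        # own empty-text warnings while probing.
        prev = logger.disabled
        logger.disabled = True
        try:
            for probe in PROBE_TEXTS:
                val = float(contract.score(probe))
                if not math.isfinite(val) or not -1.0 <= val <= 1.0:
                    raise ValueError(
                        f"scorer {contract.name!r} refused: probe {probe[:30]!r} "
                        f"scored {val!r}, outside [-1, 1]"
                    )
        finally:
            logger.disabled = prev
        self._scorers[contract.name] = contract
        return contract.name

    def get(self, name: str) -> ScorerContract:
        try:
            return self._scorers[name]
        except KeyError:
            raise KeyError(
                f"no scorer registered under {name!r}; "
                f"available: {sorted(self._scorers)}"
            ) from None

    def names(self) -> list[str]:
        return sorted(self._scorers)


def default_registry(
    lexicon: Optional[ValenceLexicon] = None,
    params: ScorerParams = DEFAULT_PARAMS,
) -> ScorerRegistry:
    """A registry with the two built-in channels: ``lexicon_a`` (saturating
    sum) and ``lexicon_b`` (averaging), sharing one dictionary."""
    lex = lexicon if lexicon is not None else load_fixture_lexicon()
    reg = ScorerRegistry()
    reg.register(
        ScorerContract("lexicon_a", lambda t: score_text(t, lex, params))
    )
    reg.register(
        ScorerContract("lexicon_b", lambda t: average_score_text(t, lex, params))
    )
    return reg
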