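"""Hybrid rule-based ensemble sentiment classifier.

The architecture fuses three channels per post:

1. two continuous lexicon polarity channels, combined by a weighted
   average ``w_a * s_a + w_b * s_b`` (defaults 0.48 / 0.52);
2. the combined score mapped to a 3-class label by symmetric thresholds
   (default +/-0.05 on the normalised [-1, 1] scale);
3. a contextual classifier channel (in production a pretrained
   transformer; in the core test suite a deterministic keyword-table
   stand-in), fused with the lexicon label by an if/else rule: when the
   lexicon ensemble says *positive*, the lexicon label is final; otherwise
   the contextual channel's label is final.

The fusion rule reflects a validated division of labour: the lexicon
ensemble is the more accurate judge of positive sentiment, the contextual
channel of neutral and negative sentiment.

Weight tuning evaluates the full ensemble on a labelled sample over a
one-parameter grid (``w_b = 1 - w_a``) and selects the weight maximising
macro-averaged recall, with ties broken toward equal weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .lexicon import ScorerRegistry, default_registry, tokenize
from .models import CLASS_ORDER, Post, ScoredPost, SentimentLabel

__all__ = [
    "EnsembleConfig",
    "ContextualClassifier",
    "KeywordTableClassifier",
    "ConfusionMatrix",
    "combine_lexicon",
    "score_to_label",
    "fuse",
    "classify_corpus",
    "tune_weights",
    "validate",
    "DEFAULT_WEIGHT_GRID",
]

logger = logging.getLogger(__name__)

POS, NEU, NEG = CLASS_ORDER


@dataclass(frozen=True)
class ContextualClassifier:
    """A pluggable label-valued channel: ``classify(text)`` returns one of
    the three sentiment labels; ``deterministic`` promises repeatability."""

    name: str
    classify: Callable[[str], SentimentLabel]
    deterministic: bool = True


def KeywordTableClassifier(
    positive_terms: Sequence[str],
    negative_terms: Sequence[str],
    name: str = "keyword_table",
) -> ContextualClassifier:
    """Deterministic keyword-table stand-in for the contextual channel.

    Labels by majority vote of positive- vs negative-marker token counts;
    neutral on a tie or when no marker appears.
    """
    pos = frozenset(t.lower() for t in positive_terms)
    neg = frozenset(t.lower() for t in negative_terms)
    overlap = pos & neg
    if overlap:
        raise ValueError(f"marker tables overlap: {sorted(overlap)[:5]}")

    def classify(text: str) -> SentimentLabel:
        toks = tokenize(text)
        n_pos = sum(t in pos for t in toks)
        n_neg = sum(t in neg for t in toks)
        if n_pos > n_neg:
            return POS
        if n_neg > n_pos:
            return NEG
        return NEU

    return ContextualClassifier(name, classify)


@dataclass(frozen=True)
class EnsembleConfig:
    """Weights, thresholds and channel wiring of the hybrid ensemble.

    ``weight_a + weight_b`` must equal 1 (the combination is a convex
    average) and the label thresholds must straddle zero.  ``positive_gate``
    selects which channel's *positive* triggers the lexicon-governed
    branch of the fusion rule: ``"lexicon"`` (default) or ``"contextual"``.
    """

    weight_a: float = 0.48
    weight_b: float = 0.52
    positive_threshold: float = 0.05
    negative_threshold: float = -0.05
    channel_a: str = "lexicon_a"
    channel_b: str = "lexicon_b"
    contextual: Optional[ContextualClassifier] = None
    positive_gate: str = "lexicon"

    def __post_init__(self) -> None:
        if abs(self.weight_a + self.weight_b - 1.0) > 1e-12:
            raise ValueError(
                f"weights must sum to 1; got {self.weight_a} + {self.weight_b}"
            )
        if not (0.0 <= self.weight_a <= 1.0):
            raise ValueError("weight_a must be in [0, 1]")
        if not self.negative_threshold < 0.0 < self.positive_threshold:
            raise ValueError("thresholds must satisfy negative < 0 < positive")
        if self.positive_gate not in ("lexicon", "contextual"):
            raise ValueError(f"unknown positive_gate {self.positive_gate!r}")

    def with_weight_a(self, weight_a: float) -> "EnsembleConfig":
        return replace(self, weight_a=weight_a, weight_b=1.0 - weight_a)


def combine_lexicon(
    score_a: float, score_b: float, config: EnsembleConfig
) -> float:
    """Convex weighted average of the two lexicon channels."""
    return config.weight_a * score_a + config.weight_b * score_b


def score_to_label(score: float, config: EnsembleConfig) -> SentimentLabel:
    """Threshold a continuous polarity onto the three classes.

    Positive iff ``score >= positive_threshold`` (boundary inclusive);
    negative iff ``score <= negative_threshold``; neutral otherwise.
    """
    if score >= config.positive_threshold:
        return POS
    if score <= config.negative_threshold:
        return NEG
    return NEU


def fuse(
    lexicon_label: SentimentLabel,
    lexicon_score: float,
    contextual_label: SentimentLabel,
    config: Optional[EnsembleConfig] = None,
) -> SentimentLabel:
    """If/else fusion of the lexicon-ensemble and contextual channels.

    Default (``positive_gate="lexicon"``): the lexicon label decides the
    positive branch — if it is positive the final label is positive; for
    the neutral and negative branches the contextual label is final, even
    when that label is positive.  The full 3x3 rule table:

    ========  ==========  ========
    lexicon   contextual  final
    ========  ==========  ========
    positive  positive    positive
    positive  neutral     positive
    positive  negative    positive
    neutral   any         contextual
    negative  any         contextual
    ========  ==========  ========

    The alternative gate (``positive_gate="contextual"``) instead lets the
    contextual channel's *positive* select the lexicon output: final is
    the lexicon label when the contextual label is positive, else the
    contextual label.
    """
    gate = config.positive_gate if config is not None else "lexicon"
    if gate == "lexicon":
        return POS if lexicon_label is POS else contextual_label
    return lexicon_label if contextual_label is POS else contextual_label


@dataclass
class ClassificationReport:
    """Diagnostics for a corpus run: posts flagged by channel failures are
    excluded from the scored output and counted here."""

    n_input: int = 0
    n_scored: int = 0
    failures: list = field(default_factory=list)  # (post_id, error string)


def classify_corpus(
    posts: Sequence[Post],
    config: EnsembleConfig,
    registry: Optional[ScorerRegistry] = None,
    report: Optional[ClassificationReport] = None,
) -> list[ScoredPost]:
    """Run the full ensemble over a corpus.

    Each post carries both lexicon scores, the combined score, the lexicon
    label, the contextual label and the fused final label.  A channel
    failure on a post flags the post (collected in ``report``) and excludes
    it from the output; it never aborts the run.
    """
    if config.contextual is None:
        raise ValueError("config.contextual channel is not set")
    reg = registry if registry is not None else default_registry()
    scorer_a = reg.get(config.channel_a)
    scorer_b = reg.get(config.channel_b)
    out: list[ScoredPost] = []
    rep = report if report is not None else ClassificationReport()
    rep.n_input += len(posts)
    for post in posts:
        try:
            sa = float(scorer_a.score(post.text))
            sb = float(scorer_b.score(post.text))
            combined = combine_lexicon(sa, sb, config)
            lex_label = score_to_label(combined, config)
            ctx_label = config.contextual.classify(post.text)
            final = fuse(lex_label, combined, ctx_label, config)
            out.append(
                ScoredPost(post, sa, sb, combined, lex_label, ctx_label, final)
            )
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            rep.failures.append((post.post_id, str(exc)))
            logger.warning("channel failure on post %s: %s", post.post_id, exc)
    rep.n_scored += len(out)
    return out


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 confusion counts, rows = gold, columns = predicted, class order
    fixed as (positive, neutral, negative)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (3, 3) or (arr < 0).any():
            raise ValueError("counts must be a 3x3 grid of non-negative integers")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_labels(
        cls,
        gold: Sequence[SentimentLabel],
        predicted: Sequence[SentimentLabel],
    ) -> "ConfusionMatrix":
        order = [c.value for c in CLASS_ORDER]
        arr = _sk_confusion(
            [g.value for g in gold], [p.value for p in predicted], labels=order
        )
        return cls(arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def sensitivity(self) -> dict[SentimentLabel, float]:
        """One-vs-rest per-class sensitivity TP / (TP + FN)."""
        out = {}
        for i, cls_ in enumerate(CLASS_ORDER):
            tp = self.counts[i, i]
            fn = self.counts[i, :].sum() - tp
            out[cls_] = float(tp / (tp + fn)) if tp + fn else float("nan")
        return out

    def specificity(self) -> dict[SentimentLabel, float]:
        """One-vs-rest per-class specificity TN / (TN + FP)."""
        out = {}
        for i, cls_ in enumerate(CLASS_ORDER):
            fp = self.counts[:, i].sum() - self.counts[i, i]
            tn = self.total - self.counts[i, :].sum() - fp
            out[cls_] = float(tn / (tn + fp)) if tn + fp else float("nan")
        return out

    def macro_recall(self) -> float:
        """Mean one-vs-rest sensitivity over the three classes."""
        sens = [v for v in self.sensitivity().values() if v == v]
        return float(np.mean(sens)) if sens else float("nan")

    def to_text(self) -> str:
        header = "gold\\pred\t" + "\t".join(c.value for c in CLASS_ORDER)
        rows = [
            c.value + "\t" + "\t".join(str(int(x)) for x in self.counts[i])
            for i, c in enumerate(CLASS_ORDER)
        ]
        return "\n".join([header] + rows) + "\n"


def validate(
    scored: Sequence[ScoredPost],
) -> tuple[ConfusionMatrix, dict[SentimentLabel, dict[str, float]]]:
    """Confusion matrix and per-class one-vs-rest sensitivity/specificity
    of the fused labels against gold labels."""
    missing = [sp.post.post_id for sp in scored if sp.post.gold_label is None]
    if missing:
        raise ValueError(
            f"{len(missing)} post(s) lack a gold label (e.g. {missing[:3]})"
        )
    cm = ConfusionMatrix.from_labels(
        [sp.post.gold_label for sp in scored], [sp.final_label for sp in scored]
    )
    sens, spec = cm.sensitivity(), cm.specificity()
    metrics = {
        cls_: {"sensitivity": sens[cls_], "specificity": spec[cls_]}
        for cls_ in CLASS_ORDER
    }
    return cm, metrics


#: Default tuning grid for weight_a; weight_b is its complement.
DEFAULT_WEIGHT_GRID = tuple(round(0.40 + 0.02 * i, 2) for i in range(11))


def tune_weights(
    labelled: Sequence[Post],
    config_base: EnsembleConfig,
    grid: Sequence[float] = DEFAULT_WEIGHT_GRID,
    registry: Optional[ScorerRegistry] = None,
) -> tuple[EnsembleConfig, dict[float, ConfusionMatrix]]:
    """Grid-search the lexicon weight on a gold-labelled sample.

    Evaluates the full ensemble at each ``weight_a`` grid point and selects
    the weight maximising macro-averaged recall over the three classes.
    Ties break toward equal weights (closest to 0.5, then the smaller
    weight).  Returns the tuned config and per-weight confusion matrices.
    """
    if not labelled:
        raise ValueError("labelled set is empty")
    missing_gold = [p.post_id for p in labelled if p.gold_label is None]
    if missing_gold:
        raise ValueError(f"{len(missing_gold)} labelled post(s) lack gold_label")
    present = {p.gold_label for p in labelled}
    absent = [c.value for c in CLASS_ORDER if c not in present]
    if absent:
        raise ValueError(f"labelled set is missing class(es): {absent}")
    if not grid or any(not 0.0 <= w <= 1.0 for w in grid):
        raise ValueError("grid must be a non-empty subset of [0, 1]")

    reg = registry if registry is not None else default_registry()
    # Channel outputs do not depend on the weights: score once, reuse.
    scorer_a, scorer_b = reg.get(config_base.channel_a), reg.get(config_base.channel_b)
    if config_base.contextual is None:
        raise ValueError("config_base.contextual channel is not set")
    sa = np.array([float(scorer_a.score(p.text)) for p in labelled])
    sb = np.array([float(scorer_b.score(p.text)) for p in labelled])
    ctx = [config_base.contextual.classify(p.text) for p in labelled]
    gold = [p.gold_label for p in labelled]

    diagnostics: dict[float, ConfusionMatrix] = {}
    scores: dict[float, float] = {}
    for w in grid:
        cfg = config_base.with_weight_a(float(w))
        combined = cfg.weight_a * sa + cfg.weight_b * sb
        final = [
            fuse(score_to_label(c, cfg), c, ctx_label, cfg)
            for c, ctx_label in zip(combined, ctx)
        ]
        cm = ConfusionMatrix.from_labels(gold, final)
        diagnostics[float(w)] = cm
        scores[float(w)] = cm.macro_recall()

    best = max(
        scores,
        key=lambda w: (scores[w], -abs(w - 0.5), -w),
    )
    logger.info("tuned weight_a=%.2f (macro recall %.4f)", best, scores[best])
    return config_base.with_weight_a(best), diagnostics
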