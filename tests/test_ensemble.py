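"""Hybrid ensemble: weighted averaging, thresholding, the 9-cell fusion
rule table, corpus classification, weight tuning and validation math."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sentitrace.ensemble import (
    ConfusionMatrix,
    EnsembleConfig,
    KeywordTableClassifier,
    classify_corpus,
    combine_lexicon,
    fuse,
    score_to_label,
    tune_weights,
    validate,
)
from sentitrace.lexicon import ScorerContract, ScorerRegistry
from sentitrace.models import CLASS_ORDER, SentimentLabel

POS, NEU, NEG = CLASS_ORDER

#: Independent oracle for the fusion rule: (lexicon, contextual) -> final.
#: The lexicon ensemble governs the positive branch; otherwise the
#: contextual channel's output is final, even when that output is positive.
FUSION_ORACLE = {
    (POS, POS): POS,
    (POS, NEU): POS,
    (POS, NEG): POS,
    (NEU, POS): POS,
    (NEU, NEU): NEU,
    (NEU, NEG): NEG,
    (NEG, POS): POS,
    (NEG, NEU): NEU,
    (NEG, NEG): NEG,
}


class TestEnsembleConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EnsembleConfig(weight_a=0.48, weight_b=0.51)

    def test_thresholds_must_straddle_zero(self):
        with pytest.raises(ValueError, match="threshold"):
            EnsembleConfig(positive_threshold=-0.1, negative_threshold=-0.2)

    def test_default_weights_are_048_052(self):
        cfg = EnsembleConfig()
        assert (cfg.weight_a, cfg.weight_b) == (0.48, 0.52)


class TestCombineLexicon:
    def test_equal_inputs_are_a_fixed_point(self):
        assert combine_lexicon(0.5, 0.5, EnsembleConfig()) == pytest.approx(0.5)

    def test_published_weights_direct_arithmetic(self):
        assert combine_lexicon(1.0, 0.0, EnsembleConfig()) == pytest.approx(0.48)
        assert combine_lexicon(0.0, 1.0, EnsembleConfig()) == pytest.approx(0.52)

    def test_simple_average_case(self):
        cfg = EnsembleConfig(weight_a=0.5, weight_b=0.5)
        assert combine_lexicon(-0.2, 0.6, cfg) == pytest.approx(0.2)

    def test_affine_in_first_argument(self):
        cfg = EnsembleConfig()
        a, b, delta = 0.25, -0.5, 0.125  # exact binary fractions
        assert combine_lexicon(a + delta, b, cfg) - combine_lexicon(a, b, cfg) == (
            pytest.approx(cfg.weight_a * delta, abs=1e-15)
        )


class TestScoreToLabel:
    CFG = EnsembleConfig()

    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.0, NEU),
            (0.05, POS),  # boundary is inclusive on the positive side
            (-0.05, NEG),
            (0.049999, NEU),
            (-0.06, NEG),
            (1.0, POS),
            (-1.0, NEG),
        ],
    )
    def test_threshold_mapping(self, score, expected):
        assert score_to_label(score, self.CFG) is expected


class TestFuse:
    def test_all_nine_cells_match_oracle_table(self):
        for lex, ctx in itertools.product(CLASS_ORDER, repeat=2):
            assert fuse(lex, 0.0, ctx) is FUSION_ORACLE[(lex, ctx)], (lex, ctx)

    def test_positive_lexicon_overrides_contextual(self):
        assert fuse(POS, 0.6, NEG) is POS

    def test_non_positive_lexicon_defers_to_contextual(self):
        assert fuse(NEU, 0.01, NEG) is NEG
        assert fuse(NEG, -0.3, POS) is POS

    def test_contextual_gate_alternative_interpretation(self):
        cfg = EnsembleConfig(positive_gate="contextual")
        # Contextual "positive" selects the lexicon output...
        assert fuse(NEG, -0.3, POS, cfg) is NEG
        assert fuse(POS, 0.3, POS, cfg) is POS
        # ...otherwise the contextual label is final.
        assert fuse(POS, 0.3, NEG, cfg) is NEG

    def test_identical_channels_make_fusion_identity(self):
        for label in CLASS_ORDER:
            assert fuse(label, 0.0, label) is label


def _cell_registry_and_config():
    """Channels driven by magic tokens so each of the 9 cells is reachable."""

    def lex_score(text: str) -> float:
        toks = text.split()
        return {"lexpos": 0.6, "lexneu": 0.0, "lexneg": -0.6}.get(
            toks[0] if toks else "", 0.0
        )

    def ctx(text: str) -> SentimentLabel:
        toks = text.split()
        return {"ctxpos": POS, "ctxneu": NEU, "ctxneg": NEG}.get(
            toks[1] if len(toks) > 1 else "", NEU
        )

    reg = ScorerRegistry()
    reg.register(ScorerContract("ctrl_a", lex_score))
    reg.register(ScorerContract("ctrl_b", lex_score))
    from sentitrace.ensemble import ContextualClassifier

    cfg = EnsembleConfig(
        channel_a="ctrl_a",
        channel_b="ctrl_b",
        contextual=ContextualClassifier("ctrl_ctx", ctx),
    )
    return reg, cfg


class TestClassifyCorpus:
    def test_nine_cell_fixture_matches_rule_table(self, make_post):
        reg, cfg = _cell_registry_and_config()
        lex_tok = {POS: "lexpos", NEU: "lexneu", NEG: "lexneg"}
        ctx_tok = {POS: "ctxpos", NEU: "ctxneu", NEG: "ctxneg"}
        cells = list(itertools.product(CLASS_ORDER, repeat=2))
        posts = [make_post(f"{lex_tok[l]} {ctx_tok[c]}") for l, c in cells]
        scored = classify_corpus(posts, cfg, registry=reg)
        assert [sp.final_label for sp in scored] == [
            FUSION_ORACLE[cell] for cell in cells
        ]
        assert [sp.lexicon_label for sp in scored] == [l for l, _ in cells]
        assert [sp.contextual_label for sp in scored] == [c for _, c in cells]

    def test_empty_corpus(self, ensemble_config, registry):
        assert classify_corpus([], ensemble_config, registry=registry) == []

    def test_duplicate_texts_score_identically(self, ensemble_config, registry, make_post):
        posts = [make_post("wonderful helpful covid app"), make_post("wonderful helpful covid app")]
        a, b = classify_corpus(posts, ensemble_config, registry=registry)
        assert (a.lexicon_ensemble_score, a.final_label) == (
            b.lexicon_ensemble_score,
            b.final_label,
        )
        assert a.post.post_id != b.post.post_id

    def test_channel_failure_flags_post_not_run(self, make_post):
        from sentitrace.ensemble import ClassificationReport, ContextualClassifier

        def fragile(text: str) -> float:
            if "boom" in text:
                raise RuntimeError("scorer exploded")
            return 0.5

        reg = ScorerRegistry()
        reg.register(ScorerContract("fragile", fragile))
        cfg = EnsembleConfig(
            channel_a="fragile",
            channel_b="fragile",
            contextual=ContextualClassifier("c", lambda t: NEU),
        )
        report = ClassificationReport()
        posts = [make_post("fine text"), make_post("boom here")]
        scored = classify_corpus(posts, cfg, registry=reg, report=report)
        assert len(scored) == 1
        assert report.n_input == 2 and report.n_scored == 1
        assert report.failures[0][0] == posts[1].post_id


class TestConfusionMatrixMath:
    # Printed 3x3 fixture (rows gold, cols predicted; order pos/neu/neg).
    FIXTURE = np.array([[40, 7, 3], [5, 30, 5], [2, 8, 40]])

    def test_one_vs_rest_sensitivity_hand_computed(self):
        cm = ConfusionMatrix(self.FIXTURE)
        sens = cm.sensitivity()
        assert sens[POS] == 40 / 50
        assert sens[NEU] == 30 / 40
        assert sens[NEG] == 40 / 50

    def test_one_vs_rest_specificity_hand_computed(self):
        cm = ConfusionMatrix(self.FIXTURE)
        spec = cm.specificity()
        # positive: FP = 5 + 2 = 7, TN = 140 - 50 - 7 = 83.
        assert spec[POS] == 83 / 90
        # neutral: FP = 7 + 8 = 15, TN = 140 - 40 - 15 = 85.
        assert spec[NEU] == 85 / 100
        # negative: FP = 3 + 5 = 8, TN = 140 - 50 - 8 = 82.
        assert spec[NEG] == 82 / 90

    def test_total_and_macro_recall(self):
        cm = ConfusionMatrix(self.FIXTURE)
        assert cm.total == 140
        assert cm.macro_recall() == pytest.approx((0.8 + 0.75 + 0.8) / 3)

    def test_perfect_predictions_are_diagonal(self, make_scored):
        scored = []
        for label in CLASS_ORDER:
            for _ in range(10):
                sp = make_scored(0.5, final_label=label, gold_label=label)
                scored.append(sp)
        cm, metrics = validate(scored)
        assert np.trace(cm.counts) == 30 and cm.total == 30
        for cls_ in CLASS_ORDER:
            assert metrics[cls_]["sensitivity"] == 1.0
            assert metrics[cls_]["specificity"] == 1.0

    def test_degenerate_all_neutral_predictor(self, make_scored):
        scored = [
            make_scored(0.0, final_label=NEU, gold_label=g)
            for g in CLASS_ORDER
            for _ in range(5)
        ]
        cm, metrics = validate(scored)
        assert metrics[NEU]["sensitivity"] == 1.0
        assert metrics[POS]["sensitivity"] == 0.0
        assert metrics[NEG]["sensitivity"] == 0.0

    def test_validate_requires_gold_labels(self, make_scored):
        with pytest.raises(ValueError, match="gold label"):
            validate([make_scored(0.5)])


def _dominant_b_setup(make_post):
    """Labelled set where channel B is a perfect polarity oracle and
    channel A is its exact anti-correlate.  The combined score is
    (w_b - w_a) * g, so smaller weight_a keeps more positives above the
    labelling threshold: macro recall strictly decreases along the grid."""
    from sentitrace.ensemble import ContextualClassifier

    magnitudes = [0.26, 0.32, 0.45, 0.60, 0.80, 1.0]
    posts, truth = [], {}
    i = 0
    for sign, label in ((1, POS), (-1, NEG)):
        for mag in magnitudes:
            p = make_post(f"g {sign * mag}", post_id=f"dom{i}", gold_label=label)
            posts.append(p)
            i += 1
    for _ in range(6):
        posts.append(make_post("g 0.0", post_id=f"dom{i}", gold_label=NEU))
        i += 1

    def score_b(text: str) -> float:
        toks = text.split()
        try:
            return float(toks[1])
        except (IndexError, ValueError):
            return 0.0

    reg = ScorerRegistry()
    reg.register(ScorerContract("anti_a", lambda t: -score_b(t)))
    reg.register(ScorerContract("perfect_b", score_b))
    cfg = EnsembleConfig(
        channel_a="anti_a",
        channel_b="perfect_b",
        contextual=ContextualClassifier("always_neutral", lambda t: NEU),
    )
    return posts, reg, cfg


class TestTuneWeights:
    GRID = tuple(round(0.40 + 0.02 * i, 2) for i in range(11))

    def test_dominant_channel_b_selects_grid_minimum(self, make_post):
        posts, reg, cfg = _dominant_b_setup(make_post)
        best, diagnostics = tune_weights(posts, cfg, grid=self.GRID, registry=reg)
        assert best.weight_a == 0.40
        # Exhaustive independent evaluation: recall must be non-increasing
        # in weight_a and strictly lower at the top of the grid.
        recalls = [diagnostics[w].macro_recall() for w in self.GRID]
        assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))
        assert recalls[0] > recalls[-1]

    def test_identical_channels_tie_break_returns_half(self, make_post, registry, vocab):
        cfg = EnsembleConfig(
            channel_a="lexicon_a",
            channel_b="lexicon_a",
            contextual=KeywordTableClassifier(vocab.positive, vocab.negative),
        )
        posts = [
            make_post("wonderful great covid app", gold_label=POS),
            make_post("terrible awful covid app", gold_label=NEG),
            make_post("phone update covid app", gold_label=NEU),
        ]
        grid = (0.4, 0.44, 0.5, 0.56, 0.6)
        best, diagnostics = tune_weights(posts, cfg, grid=grid, registry=registry)
        assert best.weight_a == 0.5
        assert len({cm.macro_recall() for cm in diagnostics.values()}) == 1

    def test_singleton_grid_returns_that_weight(self, make_post, registry, vocab):
        cfg = EnsembleConfig(
            contextual=KeywordTableClassifier(vocab.positive, vocab.negative)
        )
        posts = [
            make_post("wonderful covid app", gold_label=POS),
            make_post("awful covid app", gold_label=NEG),
            make_post("phone covid app", gold_label=NEU),
        ]
        best, _ = tune_weights(posts, cfg, grid=(0.48,), registry=registry)
        assert (best.weight_a, best.weight_b) == (0.48, 0.52)

    def test_channel_swap_symmetry(self, make_post):
        posts, reg, cfg = _dominant_b_setup(make_post)
        best, _ = tune_weights(posts, cfg, grid=self.GRID, registry=reg)
        from dataclasses import replace

        swapped_cfg = replace(cfg, channel_a="perfect_b", channel_b="anti_a")
        swapped_best, _ = tune_weights(
            posts, swapped_cfg, grid=self.GRID, registry=reg
        )
        assert swapped_best.weight_a == pytest.approx(1.0 - best.weight_a)

    def test_missing_class_raises_naming_it(self, make_post, registry, vocab):
        cfg = EnsembleConfig(
            contextual=KeywordTableClassifier(vocab.positive, vocab.negative)
        )
        posts = [
            make_post("wonderful covid app", gold_label=POS),
            make_post("phone covid app", gold_label=NEU),
        ]
        with pytest.raises(ValueError, match="negative"):
            tune_weights(posts, cfg, registry=registry)
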