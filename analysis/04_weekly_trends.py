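#!/usr/bin/env python
"""Weekly sentiment trends and the planted step-change check.

Computes overall class proportions and the combined (pooled) weekly
sentiment series for the scored main corpus, then classifies the
step-trend corpus and tests whether the planted jump in negative
sentiment at ISO week 2020-W20 is recovered (two-proportion z-test).
"""

import json
from pathlib import Path

from statsmodels.stats.proportion import proportions_ztest

from sentitrace.aggregation import overall_proportions, weekly_series
from sentitrace.ensemble import EnsembleConfig, KeywordTableClassifier, classify_corpus
from sentitrace.io import read_posts, read_scored
from sentitrace.lexicon import default_registry
from sentitrace.models import CLASS_ORDER
from sentitrace.synthetic import default_vocab

DATA = Path("results/data")
STEP = (2020, 20)


def write_series(series, path: Path) -> None:
    path.write_text(
        "iso_year\tiso_week\tn_a\tn_b\tmean_score\tprop_positive\t"
        "prop_neutral\tprop_negative\n"
        + "".join(
            f"{w.iso_year}\t{w.iso_week}\t{w.n_a}\t{w.n_b}\t{w.mean_score:.6f}\t"
            f"{w.prop_positive:.4f}\t{w.prop_neutral:.4f}\t{w.prop_negative:.4f}\n"
            for w in series if not w.empty
        )
    )


def main() -> None:
    scored = read_scored(DATA / "scored_main.csv")
    props = overall_proportions(scored)
    Path("results/overall_proportions.json").write_text(
        json.dumps({c.value: round(props[c], 4) for c in CLASS_ORDER}, indent=2) + "\n"
    )
    series = weekly_series(scored)
    write_series(series, Path("results/weekly_series.tsv"))
    print("overall: " + ", ".join(f"{c.value} {100 * props[c]:.1f}%" for c in CLASS_ORDER))
    print(f"weekly series: {len(series)} ISO-week bins "
          f"({series[0].iso_year}-W{series[0].iso_week:02d} .. "
          f"{series[-1].iso_year}-W{series[-1].iso_week:02d})")

    # Step-change recovery on the trend corpus.
    vocab = default_vocab()
    cfg = EnsembleConfig(contextual=KeywordTableClassifier(vocab.positive, vocab.negative))
    trend_scored = classify_corpus(read_posts(DATA / "corpus_step.csv"), cfg,
                                   registry=default_registry())
    write_series(weekly_series(trend_scored), Path("results/weekly_series_step.tsv"))
    pre = [0, 0]
    post = [0, 0]
    for w in weekly_series(trend_scored):
        if w.empty:
            continue
        bucket = pre if (w.iso_year, w.iso_week) < STEP else post
        bucket[0] += round(w.prop_negative * w.n)
        bucket[1] += w.n
    z, p = proportions_ztest([pre[0], post[0]], [pre[1], post[1]], alternative="smaller")
    print(f"step change at 2020-W{STEP[1]}: negative share "
          f"{100 * pre[0] / pre[1]:.1f}% -> {100 * post[0] / post[1]:.1f}% "
          f"(z = {z:.2f}, p = {p:.2e})")


if __name__ == "__main__":
    main()
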