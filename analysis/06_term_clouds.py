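#!/usr/bin/env python
"""Sentiment-conditional term-frequency tables (word-cloud data).

For each final sentiment class, counts the most frequent terms after
removing stopwords and the thematic filter keywords themselves, and
writes one ranked table per class."""

from pathlib import Path

from sentitrace.aggregation import term_frequencies
from sentitrace.filtering import default_app_spec, default_covid_spec
from sentitrace.io import read_scored
from sentitrace.models import CLASS_ORDER

DATA = Path("results/data")


def main() -> None:
    scored = read_scored(DATA / "scored_main.csv")
    exclude = default_app_spec().keywords + default_covid_spec().keywords
    for cls_ in CLASS_ORDER:
        table = term_frequencies(scored, label=cls_, exclude_terms=exclude, top_k=30)
        path = Path(f"results/terms_{cls_.value}.tsv")
        path.write_text(
            "term\tcount\n" + "".join(f"{t}\t{c}\n" for t, c in table.entries)
        )
        head = ", ".join(t for t, _ in table.entries[:8])
        print(f"{cls_.value}: {head}  ({len(table.entries)} terms -> {path})")


if __name__ == "__main__":
    main()
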