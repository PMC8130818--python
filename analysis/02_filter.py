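#!/usr/bin/env python
"""Build the analysis corpus: two-step thematic filter plus corpus window.

Reads results/data/corpus_main.csv, applies the pandemic-keyword first
step, the 11 contact-tracing-app keywords second, then the March–October
2020 English-language window, and writes the retained posts with a
stage-by-stage count table.
"""

import datetime as dt
from pathlib import Path

from sentitrace.filtering import (
    CorpusWindow,
    apply_keyword_filter,
    apply_window,
    default_app_spec,
    default_covid_spec,
)
from sentitrace.io import read_posts, write_posts

DATA = Path("results/data")


def main() -> None:
    posts = read_posts(DATA / "corpus_main.csv")
    step1 = apply_keyword_filter(posts, default_covid_spec())
    step2 = apply_keyword_filter(step1, default_app_spec())
    window = CorpusWindow(dt.date(2020, 3, 1), dt.date(2020, 10, 31), "en")
    final = apply_window(step2, window)
    write_posts(final, DATA / "corpus_filtered.csv")

    table = Path("results/filter_counts.tsv")
    table.write_text(
        "stage\tretained\n"
        f"ingested\t{len(posts)}\n"
        f"covid_keywords\t{len(step1)}\n"
        f"app_keywords\t{len(step2)}\n"
        f"window\t{len(final)}\n"
    )
    print(f"ingested {len(posts)} -> covid {len(step1)} -> app {len(step2)} "
          f"-> window {len(final)} posts (counts in {table})")


if __name__ == "__main__":
    main()
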