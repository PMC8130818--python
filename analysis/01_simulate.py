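#!/usr/bin/env python
"""Generate the study-shaped synthetic corpora.

Writes two corpora under results/data/:
  * corpus_main.csv  — 10,000 posts, 80/20 platform split, 76/12/12
    positive/neutral/negative gold proportions, March 1 – October 31 2020.
  * corpus_step.csv  — 3,000 posts with a planted jump in the negative
    class (10% -> 30%) at ISO week 2020-W20, emulating a mid-May shift in
    the public debate.
"""

import datetime as dt
from pathlib import Path

from sentitrace.io import write_posts
from sentitrace.synthetic import GeneratorSpec, generate_corpus, step_schedule

OUT = Path("results/data")
SEED = 20_2003


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = GeneratorSpec(n_posts=10_000, seed=SEED)
    corpus = generate_corpus(spec)
    write_posts(corpus, OUT / "corpus_main.csv")
    print(f"corpus_main: {len(corpus)} posts, "
          f"{spec.start_date} .. {spec.end_date}, seed {spec.seed}")

    sched = step_schedule(
        dt.date(2020, 3, 1), dt.date(2020, 10, 31),
        step_week=(2020, 20), before=(0.80, 0.10, 0.10), after=(0.60, 0.10, 0.30),
    )
    step_spec = GeneratorSpec(n_posts=3_000, weekly_trend=sched, seed=SEED + 1)
    step_corpus = generate_corpus(step_spec)
    write_posts(step_corpus, OUT / "corpus_step.csv")
    print(f"corpus_step: {len(step_corpus)} posts with negative-class step "
          "10% -> 30% at 2020-W20")


if __name__ == "__main__":
    main()
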