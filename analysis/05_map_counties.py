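#!/usr/bin/env python
"""County-level sentiment mapping tables.

Aggregates the geo-tagged subset of the scored corpus per UK county and
writes the choropleth input table plus top-5 most-positive and
most-negative county rankings (minimum 5 posts per county)."""

from pathlib import Path

from sentitrace.aggregation import rank_regions, region_summaries
from sentitrace.io import read_scored
from sentitrace.synthetic import load_uk_counties

DATA = Path("results/data")


def main() -> None:
    scored = read_scored(DATA / "scored_main.csv")
    counties = load_uk_counties()
    summaries, n_unresolved = region_summaries(scored, region_ids=sorted(counties))
    Path("results/county_sentiment.tsv").write_text(
        "region_id\tname\tn_posts\tmean_score\tprop_positive\tprop_negative\n"
        + "".join(
            f"{s.region_id}\t{counties.get(s.region_id, s.region_id)}\t{s.n_posts}\t"
            f"{s.mean_score:.4f}\t{s.prop_positive:.4f}\t{s.prop_negative:.4f}\n"
            for s in summaries if s.n_posts > 0
        )
    )
    n_geo = sum(s.n_posts for s in summaries)
    print(f"{n_geo} geo-tagged posts mapped to {sum(s.n_posts > 0 for s in summaries)} "
          f"counties; {n_unresolved} posts lacked geographic metadata")
    for most in ("positive", "negative"):
        top = rank_regions(summaries, k=5, most=most, min_n=5)
        names = ", ".join(f"{counties[s.region_id]} ({s.mean_score:+.3f})" for s in top)
        print(f"most {most}: {names}")


if __name__ == "__main__":
    main()
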