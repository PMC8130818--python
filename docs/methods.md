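# Methods

## Scope and pipeline

`sentitrace` implements a sentiment-surveillance analysis for social-media
discourse about contact-tracing apps: corpus construction by thematic and
window filtering, per-post 3-class sentiment via a hybrid rule-based
ensemble, validation/tuning against a labelled sample, and aggregation
into weekly series, county summaries and term-frequency tables. The unit
of analysis is the post; one label per post.

## Corpus filters

**Two-step thematic filter.** Step one is a broad pandemic keyword pass
(configurable; upstream platform exports usually arrive pre-filtered by
their own pandemic keyword lists, so the packaged default —
covid/covid19/coronavirus/sars-cov-2/pandemic/lockdown — is a stand-in,
not a canonical vocabulary). Step two is the fixed 11-phrase
contact-tracing-app list ("covid app", "tracing app", "contact tracing",
"privacy", "security", "app security", "app privacy", "contain virus
spread", "movement tracking", "tracking", "surveillance"). Matching is
`token_phrase` by default: the phrase must match whole word tokens after
case-folding, with any punctuation/whitespace run between phrase words, so
"tracking!" matches but "backtracking" does not. Substring matching is
available by flag; for short keywords like "tracking" it inflates false
positives, which is why it is not the default. Filters are order-preserving
subsequence selectors, idempotent, and monotone in the keyword set.

**Window filter.** Inclusive on both ends, evaluated on the UTC calendar
date (default March 1 – October 31 2020). Language uses the declared
per-post field when present; posts without one are retained with a warning
(language identification is deliberately out of scope). Posts without any
geographic metadata pass the window filter but are excluded later from
spatial aggregation only.

## Lexicon scoring

The dictionary maps lowercase terms to valences in [−4, 4], with booster
(intensifier) increments and a negator set; the three tables are disjoint.
Tokenisation strips URLs and @-mentions, splits hashtags off their marker,
lower-cases, and keeps apostrophes inside tokens so contracted negators
("don't") survive. Posts are scored whole (no sentence splitting): posts
are short and the analysis wants one label per post.

Rule walk, per matched token: (1) an immediately preceding booster adds
its increment toward the token's sign; (2) a negator among the 3 preceding
tokens multiplies the adjusted valence by −0.74 — flip and dampen, since
"not good" is weaker criticism than "bad". Booster first, then negation,
so "not very good" = (1.9 + 0.293)·(−0.74). These constants (α = 15 below,
window 3, factor −0.74, booster increments ≈ 0.29) follow the established
valence-lexicon conventions this scorer family builds on.

Two channels share the walk:

* **Channel A** (`lexicon_a`): raw sum *s* of adjusted valences,
  normalised to *s*/√(*s*² + 15). Saturates toward ±1 as evidence
  accumulates; exactly 0 with no dictionary hits.
* **Channel B** (`lexicon_b`): mean adjusted valence divided by 4,
  clipped to [−1, 1]. Length-invariant, so it complements A's
  length-sensitivity; the weighted ensemble is what reconciles them.

Optional all-caps/exclamation emphasis exists behind a flag, default off,
to keep the default scorer minimal and auditable.

The packaged dictionary (~300 terms, 21 boosters, 37 negators) is an
original small vocabulary written for testing and simulation; a loader
accepts full-size external dictionaries in the same 2-column format.
External scorers plug in through `ScorerContract`; registration runs a
probe battery (empty text, emoji, 1000-token repetition) and refuses any
scorer that leaves [−1, 1].

## Ensemble and fusion

The ensemble score is `w_a·s_A + w_b·s_B` with `w_a + w_b = 1`; defaults
0.48/0.52, giving slightly more weight to the averaging channel. Labels:
positive iff score ≥ +0.05 (boundary inclusive), negative iff ≤ −0.05,
neutral otherwise. ±0.05 is the common convention for normalised valence
scores; it is configurable.

Fusion with the contextual channel is the if/else rule: lexicon label
positive → final positive; otherwise the contextual label is final, *even
when that label is positive*. The phrase "for positive sentiments the
lexicon output is selected" is ambiguous about which channel's "positive"
opens that branch; we read it as the lexicon ensemble's own label (the
natural if/else construct), and expose the other reading —
contextual-positive selects the lexicon output — behind
`positive_gate="contextual"` rather than silently choosing. The full 9-cell
rule table is documented on `fuse` and enumerated in the tests.

The contextual channel is a contract (`classify(text) → label`). The core
suite and pipeline default use a deterministic keyword-table classifier
(majority vote of positive- vs negative-marker tokens, neutral on ties):
the scientific content being tested is the fusion logic and the
aggregation, not any particular pretrained model, and determinism is what
makes runs reproducible. A transformer adapter satisfies the same contract
in production use.

## Tuning and validation

`tune_weights` grid-searches `w_a` over {0.40, 0.42, …, 0.60}, evaluating
the *full* ensemble (thresholding and fusion included) on a gold-labelled
sample, and selects the weight maximising macro-averaged recall — balanced
across the three classes because the corpus is heavily positive-skewed and
plain accuracy would reward ignoring the minority classes. Ties break
toward equal weights (closest to 0.5, then the smaller `w_a`) for
reproducible selection. Channel outputs are computed once per post and
reused across the grid. Confusion matrices are 3×3 with fixed class order
(positive, neutral, negative); sensitivity and specificity are one-vs-rest
TP/(TP+FN) and TN/(TN+FP).

## Aggregation

* **Weekly series**: ISO-8601 weeks on UTC dates. The cross-platform
  "weighted" weekly average is post-count weighting, i.e. pooling: the
  week mean equals the grand mean of all that week's post scores. Equal
  platform weighting is available by flag for sensitivity analysis. Weeks
  inside the span with no posts are emitted with n = 0 and NaN mean —
  flagged, never interpolated. The March 1 – October 31 2020 span
  intersects 36 ISO weeks (2020-W09, containing only Sunday March 1,
  through 2020-W44); the first and last bins are partial.
* **Region summaries**: a post resolves via its region code, else by
  point-in-polygon (shapely) against supplied GeoJSON boundaries;
  unresolvable posts are counted and logged. Rankings exclude regions with
  fewer than 5 posts (configurable) so single-post counties cannot top the
  lists; such regions stay in the output table. Which county scheme
  (ceremonial vs administrative) applies is whatever the supplied
  lookup/boundary file encodes.
* **Term frequencies**: tokenised with the scorer's tokeniser; stopwords
  and the thematic filter keywords are excluded (the filter keywords occur
  in essentially every post by construction and would dominate every
  cloud). Ranking is count-descending with lexicographic tie-break, so
  tables are stable across runs.

## Synthetic corpus generator

The generator emulates the *shape* of a two-platform UK corpus: default
10,000 posts at an 80/20 platform split (matching the 8000 + 2000 regime
the pipeline is sized for), gold class proportions 76/12/12, the 2020
window, half the posts carrying UK county labels drawn from a packaged
36-county list. Posts are composed from class-conditional pools derived
from the packaged dictionary (|valence| ≥ 1.8 terms for the positive and
negative classes, valence-free filler for neutral), plus one pandemic
keyword and one app keyword per post so the corpus survives the two-step
filter, plus noise. A `separability` knob (default 0.9) sets the fraction
of class-informative terms per post; high separability makes gold labels
recoverable (macro recall ≥ 0.95), low separability produces hard
regimes. `weekly_trend` overrides the class proportions per ISO week, used
to plant step changes at named event weeks. All draws flow through one
seeded NumPy generator; identical spec + seed reproduces the corpus byte
for byte. The labelled validation sample is a seed-deterministic uniform
subsample without replacement (default 1000 posts).

What the generator does **not** emulate: real language (word order and
syntax are random), sarcasm and deceptive language, bots and duplicate
amplification, platform-specific formats, spatial autocorrelation of
sentiment, and class-vocabulary overlap between sentiment and topic.
Passing recovery tests therefore demonstrates that the pipeline's
machinery is correct and unbiased under known structure — not that its
accuracy transfers to real platform text, which is exactly why the
contextual channel and dictionary are pluggable.

## Numerical and degenerate-input choices

Scores are validated finite and in [−1, 1] at every boundary. Empty or
no-hit text scores exactly 0 (neutral). Timezone-naive timestamps are
rejected at ingest rather than assumed UTC, because weekly binning must be
unambiguous; all timestamps are converted to UTC. File validation is
total: every malformed row yields a line-numbered diagnostic and a file
with any bad row is rejected as a whole — no silent drops. Thresholds are
boundary-inclusive on the labelled side (score = +0.05 is positive).
Proportion triples and weights are checked to sum to 1 within 1e−12.

## Analysis problem sizes

The shipped analysis and the from-scratch reproduction script use 10,000
posts for the main corpus, 1000 labelled posts for tuning, and 3000-post
corpora (20 seeds in the test suite) for step-change recovery — sizes at
which the multinomial sampling error on a 12% class share is ±1 point and
a 10→30 point step yields a two-proportion z beyond any conventional
threshold, so the checks are decisive while the whole suite stays fast on
one CPU.

## Known limitations

* The rule-based scorer has no model of sarcasm, irony or deceptive
  language; whole-post scoring dilutes mixed-sentiment posts.
* The fusion rule is non-adaptive by design (fixed weights, fixed if/else
  table); adaptive fusion is out of scope.
* Language filtering trusts declared metadata; no language identification.
* Region assignment is point-in-polygon or exact code match only; no
  place-name geocoding.
* The packaged dictionary is deliberately small; production use should
  load a full-size valence dictionary through the same loader.
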