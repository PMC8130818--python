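"""End-to-end pipeline: simulate|ingest -> filter -> classify -> aggregate.

One run writes one immutable output directory containing every artifact
(filtered corpus, scored posts, weekly series, region summaries, term
tables, class proportions) plus a run manifest recording the config
snapshot, input digests, seeds, stage-by-stage record counts and tool
version — the audit trail a surveillance-style analysis needs.  Rerunning
an identical config and inputs reproduces identical delimited outputs.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .aggregation import (
    overall_proportions,
    region_summaries,
    term_frequencies,
    weekly_series,
)
from .ensemble import (
    ClassificationReport,
    EnsembleConfig,
    KeywordTableClassifier,
    classify_corpus,
    tune_weights,
)
from .filtering import (
    CorpusWindow,
    KeywordFilterSpec,
    apply_window,
    default_app_spec,
    default_covid_spec,
    two_step_filter,
)
from .io import read_posts, write_posts, write_scored
from .lexicon import ScorerRegistry, ValenceLexicon, default_registry, load_fixture_lexicon
from .models import CLASS_ORDER
from .synthetic import (
    GeneratorSpec,
    default_vocab,
    generate_corpus,
    generate_labelled_validation,
)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, message: str, manifest: Optional[dict] = None):
        self.stage = stage
        self.manifest = manifest or {}
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "runs"
    run_id: Optional[str] = None  # default: UTC timestamp
    input_path: Optional[str] = None  # ingest this corpus instead of simulating
    input_format: str = "csv"
    simulate: GeneratorSpec = field(default_factory=GeneratorSpec)
    lexicon_path: Optional[str] = None  # default: packaged fixture lexicon
    covid_keywords: Optional[tuple[str, ...]] = None
    app_keywords: Optional[tuple[str, ...]] = None
    window_start: dt.date = dt.date(2020, 3, 1)
    window_end: dt.date = dt.date(2020, 10, 31)
    language: Optional[str] = "en"
    weight_a: float = 0.48
    positive_threshold: float = 0.05
    negative_threshold: float = -0.05
    tune: bool = False
    n_labelled: int = 1000
    seed: Optional[int] = None  # overrides simulate.seed when set

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sim = raw.pop("simulate", None)
        for key in ("window_start", "window_end"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = dt.date.fromisoformat(raw[key])
        cfg = cls(**raw) if sim is None else cls(
            simulate=GeneratorSpec(**sim), **raw
        )
        return cfg

    def to_snapshot(self) -> dict:
        snap = dataclasses.asdict(self)
        snap["simulate"]["vocab"] = "default" if (
            self.simulate.vocab == default_vocab()
        ) else dataclasses.asdict(self.simulate.vocab)
        return json.loads(json.dumps(snap, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the run output directory.

    Any stage error aborts with :class:`PipelineError` naming the stage; a
    partial manifest (stages completed so far) is written to the run
    directory before the abort.
    """
    run_id = config.run_id or dt.datetime.now(dt.timezone.utc).strftime(
        "%Y%m%dT%H%M%SZ"
    )
    out = Path(config.out_dir) / run_id
    if out.exists() and any(out.iterdir()):
        raise PipelineError("setup", f"run directory {out} already exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "run_id": run_id,
        "tool_version": __version__,
        "started_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
        "config": config.to_snapshot(),
        "input_digests": {},
        "counts": {},
        "seeds": {},
    }

    def abort(stage: str, message: str):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
        )
        raise PipelineError(stage, message, manifest)

    # --- stage: ingest | simulate -------------------------------------
    sim_spec = config.simulate
    if config.seed is not None:
        sim_spec = sim_spec.with_(seed=config.seed)
    manifest["seeds"]["generator"] = sim_spec.seed
    if config.input_path is not None:
        src = Path(config.input_path)
        if not src.exists():
            abort("ingest", f"input file not found: {src}")
        manifest["input_digests"][str(src)] = _sha256(src)
        try:
            posts = read_posts(src, fmt=config.input_format)
        except Exception as exc:
            abort("ingest", str(exc))
    else:
        posts = generate_corpus(sim_spec)
        write_posts(posts, out / "simulated_posts.csv")
    manifest["counts"]["ingested"] = len(posts)
    logger.info("ingest: %d posts", len(posts))

    # --- stage: filter -------------------------------------------------
    covid_spec = (
        KeywordFilterSpec("covid_keywords", config.covid_keywords)
        if config.covid_keywords
        else default_covid_spec()
    )
    app_spec = (
        KeywordFilterSpec("app_keywords", config.app_keywords)
        if config.app_keywords
        else default_app_spec()
    )
    window = CorpusWindow(config.window_start, config.window_end, config.language)
    try:
        thematic = two_step_filter(posts, covid_spec, app_spec)
        filtered = apply_window(thematic, window)
    except Exception as exc:
        abort("filter", str(exc))
    manifest["counts"]["after_thematic_filter"] = len(thematic)
    manifest["counts"]["after_window_filter"] = len(filtered)
    write_posts(filtered, out / "filtered_posts.csv")
    if not filtered:
        abort("filter", "no posts survived filtering")

    # --- stage: classify (with optional tuning) ------------------------
    if config.lexicon_path is not None:
        lex_path = Path(config.lexicon_path)
        if not lex_path.exists():
            abort("classify", f"lexicon file not found: {lex_path}")
        manifest["input_digests"][str(lex_path)] = _sha256(lex_path)
        lexicon = ValenceLexicon.load(lex_path)
    else:
        lexicon = load_fixture_lexicon()
    registry = default_registry(lexicon)
    vocab = sim_spec.vocab
    contextual = KeywordTableClassifier(vocab.positive, vocab.negative)
    ens = EnsembleConfig(
        weight_a=config.weight_a,
        weight_b=round(1.0 - config.weight_a, 12),
        positive_threshold=config.positive_threshold,
        negative_threshold=config.negative_threshold,
        contextual=contextual,
    )

    if config.tune:
        labelled = generate_labelled_validation(
            sim_spec, min(config.n_labelled, len(filtered)), corpus=filtered
        )
        try:
            ens, diagnostics = tune_weights(labelled, ens, registry=registry)
        except Exception as exc:
            abort("tune", str(exc))
        manifest["counts"]["labelled_validation"] = len(labelled)
        manifest["tuned_weight_a"] = ens.weight_a
        _write_tsv(
            out / "tuning_grid.tsv",
            ["weight_a", "macro_recall"],
            [[w, cm.macro_recall()] for w, cm in sorted(diagnostics.items())],
        )
        best_cm = diagnostics[ens.weight_a]
        (out / "confusion_matrix.tsv").write_text(
            best_cm.to_text(), encoding="utf-8"
        )

    report = ClassificationReport()
    try:
        scored = classify_corpus(filtered, ens, registry=registry, report=report)
    except Exception as exc:
        abort("classify", str(exc))
    manifest["counts"]["classified"] = len(scored)
    manifest["counts"]["classify_failures"] = len(report.failures)
    write_scored(scored, out / "scored_posts.csv")

    # --- stage: aggregate ----------------------------------------------
    try:
        props = overall_proportions(scored)
        weekly = weekly_series(scored)
        regions, n_unresolved = region_summaries(scored)
        exclude = list(covid_spec.keywords) + list(app_spec.keywords)
        terms = {
            cls_.value: term_frequencies(
                scored, label=cls_, exclude_terms=exclude, top_k=50
            )
            for cls_ in CLASS_ORDER
        }
    except Exception as exc:
        abort("aggregate", str(exc))

    (out / "proportions.json").write_text(
        json.dumps({c.value: props[c] for c in CLASS_ORDER}, indent=2) + "\n",
        encoding="utf-8",
    )
    _write_tsv(
        out / "weekly_series.tsv",
        ["iso_year", "iso_week", "n_a", "n_b", "mean_score",
         "prop_positive", "prop_neutral", "prop_negative"],
        [[w.iso_year, w.iso_week, w.n_a, w.n_b, repr(w.mean_score),
          w.prop_positive, w.prop_neutral, w.prop_negative] for w in weekly],
    )
    _write_tsv(
        out / "region_summaries.tsv",
        ["region_id", "n_posts", "mean_score", "prop_positive", "prop_negative"],
        [[r.region_id, r.n_posts, repr(r.mean_score), r.prop_positive,
          r.prop_negative] for r in regions],
    )
    manifest["counts"]["geo_unresolved"] = n_unresolved
    manifest["counts"]["weekly_bins"] = len(weekly)
    for name, table in terms.items():
        _write_tsv(
            out / f"terms_{name}.tsv",
            ["term", "count"],
            [[t, c] for t, c in table.entries],
        )

    manifest["finished_utc"] = dt.datetime.now(dt.timezone.utc).isoformat()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
    )
    logger.info("pipeline run %s complete: %s", run_id, out)
    return out
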