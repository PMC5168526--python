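"""End-to-end pipeline: simulate -> dual sources -> merge -> filter ->
train -> classify -> associate -> summarize, with a run manifest.

Configuration comes from a TOML or YAML file (seed mandatory); every stage
writes its artifact into the output directory and the manifest records row
counts per stage so drops are conserved and attributable.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import platform
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytics import keyword_share, summarize_by_sentiment
from .annotation import default_schema, load_labels
from .assoc import association_scores
from .classify import (
    classify_corpus,
    fit_linear_pinv,
    fit_tree,
    loo_evaluate,
    save_models,
)
from .corpus import (
    CorpusParams,
    SourceViewParams,
    export_labels_csv,
    simulate_corpus,
    simulate_dual_sources,
    write_jsonl,
)
from .errors import ConfigError, DataError
from .features import build_feature_spec, featurize
from .merge import (
    KeywordQuery,
    dedupe_by_id,
    filter_language,
    match_keywords,
    merge_sources,
    read_tweet_stream,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    seed: int
    corpus: CorpusParams
    sources: SourceViewParams
    n_labeled: int = 1470
    vocab_size: int = 500
    certainty_threshold: float = 0.70
    min_count: int = 5
    top_terms: int = 10
    max_depth: int = 8
    min_leaf: int = 5
    language: str = "en"
    keywords: tuple[str, ...] = field(default_factory=lambda: KeywordQuery().keywords)


def _parse_gap_windows(raw) -> tuple[tuple[dt.datetime, dt.datetime], ...]:
    out = []
    for start, end in raw or []:
        def _parse(v):
            if isinstance(v, dt.datetime):
                ts = v
            elif isinstance(v, dt.date):
                ts = dt.datetime(v.year, v.month, v.day)
            else:
                ts = dt.datetime.fromisoformat(str(v))
            return ts if ts.tzinfo else ts.replace(tzinfo=dt.timezone.utc)
        out.append((_parse(start), _parse(end)))
    return tuple(out)


def load_config(path) -> PipelineConfig:
    """Read a TOML (.toml) or YAML (.yaml/.yml) pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ConfigError("config must set a seed")
    seed = int(raw["seed"])
    corpus_cfg = dict(raw.get("corpus", {}))
    corpus_cfg.setdefault("seed", seed)
    for key in (
        "sentiment_probs", "p_side_effects_given_sentiment", "p_prevention_given_sentiment",
        "p_link_given_sentiment", "p_hashtag_given_sentiment", "p_mention_given_sentiment",
        "keyword_weights",
    ):
        if key in corpus_cfg:
            corpus_cfg[key] = tuple(corpus_cfg[key])
    sources_cfg = dict(raw.get("sources", {}))
    sources_cfg.setdefault("seed", seed + 1)
    sources_cfg["gap_windows"] = _parse_gap_windows(sources_cfg.get("gap_windows"))
    try:
        corpus = CorpusParams(**corpus_cfg)
        sources = SourceViewParams(**sources_cfg)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    extra = {
        k: raw[k]
        for k in (
            "n_labeled", "vocab_size", "certainty_threshold", "min_count",
            "top_terms", "max_depth", "min_leaf", "language",
        )
        if k in raw
    }
    return PipelineConfig(seed=seed, corpus=corpus, sources=sources, **extra)


def train_models(labels, corpus_by_id, vocab_size=500, max_depth=8, min_leaf=5,
                 evaluate=True):
    """Fit the per-variable classifiers from hand-coded labels.

    Sentiment (4 classes) gets the CART tree; the binary variables get the
    pseudoinverse linear model.  Returns (models, feature_spec, eval_results).
    """
    schema = default_schema()
    labeled_records = []
    for lab in labels:
        rec = corpus_by_id.get(lab.tweet_id)
        if rec is None:
            raise DataError(f"labeled tweet {lab.tweet_id} not found in corpus")
        labeled_records.append(rec)
    spec = build_feature_spec(labeled_records, vocab_size=vocab_size)
    fm = featurize(labeled_records, spec)
    evals = {}
    models = {}
    y_sent = np.array([lab.sentiment for lab in labels])
    models["sentiment"] = fit_tree(
        fm.X, y_sent, max_depth=max_depth, min_leaf=min_leaf, target="sentiment"
    )
    if evaluate:
        evals["sentiment"] = loo_evaluate(
            fm.X, y_sent, model_kind="tree", max_depth=max_depth, min_leaf=min_leaf
        )
    for var in ("side_effects", "prevention"):
        y = np.array([lab.code(var) for lab in labels], dtype=float)
        models[var] = fit_linear_pinv(fm.X, y, target=var)
        if evaluate and np.unique(y).size >= 2:
            evals[var] = loo_evaluate(fm.X, y, model_kind="linear")
    return models, spec, evals


def build_analysis_frame(records, classified) -> pd.DataFrame:
    """Join merged-tweet metadata with kept classifications."""
    by_id = {r.tweet_id: r for r in records}
    rows = []
    for ct in classified:
        if ct.discarded:
            continue
        rec = by_id[ct.tweet_id]
        rows.append(
            {
                "tweet_id": rec.tweet_id,
                "sentiment": ct.codes["sentiment"],
                "side_effects": ct.codes["side_effects"],
                "prevention": ct.codes["prevention"],
                "user_id": rec.user_id,
                "follower_count": rec.follower_count,
                "retweet_count": rec.retweet_count,
                "has_link": bool(rec.urls),
                "has_hashtag": bool(rec.hashtags),
                "has_mention": bool(rec.mentions),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, write all artifacts, and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "counts": {},
    }
    counts = manifest["counts"]

    def stage(name):
        logger.info("pipeline stage: %s", name)

    stage("simulate")
    corpus = simulate_corpus(config.corpus)
    write_jsonl(corpus, out / "corpus.jsonl")
    counts["simulated"] = len(corpus)

    rng = np.random.default_rng(config.seed + 17)
    n_labeled = min(config.n_labeled, len(corpus))
    labeled_idx = rng.choice(len(corpus), size=n_labeled, replace=False)
    export_labels_csv([corpus[i] for i in labeled_idx], out / "labels.csv")
    counts["labeled"] = int(n_labeled)

    stage("dual-sources")
    prospective, retrospective, match_map = simulate_dual_sources(corpus, config.sources)
    write_jsonl(prospective, out / "prospective.jsonl")
    write_jsonl(retrospective, out / "retrospective.jsonl")
    counts["prospective"] = len(prospective)
    counts["retrospective"] = len(retrospective)

    stage("merge")
    prospective = dedupe_by_id(read_tweet_stream(out / "prospective.jsonl").records)
    retrospective = dedupe_by_id(read_tweet_stream(out / "retrospective.jsonl").records)
    merged, report = merge_sources(prospective, retrospective, match_map)
    report.to_json(out / "merge_report.json")
    counts["merged"] = report.n_matched

    stage("filter")
    merged = filter_language(merged, config.language)
    query = KeywordQuery(keywords=tuple(config.keywords))
    merged = [r for r in merged if match_keywords(r.text, query)]
    write_jsonl(merged, out / "merged.jsonl")
    counts["merged_english_keyword"] = len(merged)

    stage("train")
    labels = load_labels(out / "labels.csv")
    corpus_by_id = {r.tweet_id: r for r in corpus}
    models, spec, evals = train_models(
        labels, corpus_by_id,
        vocab_size=config.vocab_size,
        max_depth=config.max_depth,
        min_leaf=config.min_leaf,
        evaluate=len(labels) <= 2000,
    )
    save_models(models, out / "models.json")
    manifest["evaluation"] = {
        var: {"auc": res.auc, "error_fraction": res.error_fraction, "n": res.n}
        for var, res in evals.items()
    }

    stage("classify")
    labeled_ids = {lab.tweet_id for lab in labels}
    to_classify = [r for r in merged if r.tweet_id not in labeled_ids]
    classified, discard_report = classify_corpus(
        models, to_classify, spec, certainty_threshold=config.certainty_threshold
    )
    pd.DataFrame(
        [
            {
                "tweet_id": ct.tweet_id,
                **{v: ct.codes[v] for v in ct.codes},
                **{f"certainty_{v}": ct.certainty[v] for v in ct.certainty},
                "discarded": ct.discarded,
                "causes": ";".join(ct.causes),
            }
            for ct in classified
        ]
    ).to_csv(out / "classified.csv", index=False)
    with open(out / "discard_report.json", "w", encoding="utf-8") as fh:
        json.dump(discard_report.to_dict(), fh, indent=2)
    counts["classified"] = discard_report.n_total
    counts["kept"] = discard_report.n_kept

    stage("associate")
    assoc_dir = out / "associations"
    assoc_dir.mkdir(exist_ok=True)
    for kw in query.keywords:
        table = association_scores(merged, kw, query, min_count=config.min_count)
        slug = "".join(ch for ch in kw.lower() if ch.isalnum())
        table.to_frame().head(1000).to_csv(assoc_dir / f"{slug}.csv", index=False)

    stage("summarize")
    frame = build_analysis_frame(merged, classified)
    if len(frame):
        summary = summarize_by_sentiment(frame)
        summary.to_frame().to_csv(out / "summary.csv", index=False)
    shares = keyword_share(merged, query)
    with open(out / "keyword_shares.json", "w", encoding="utf-8") as fh:
        json.dump({k: {"count": c, "pct": p} for k, (c, p) in shares.items()}, fh, indent=2)

    # End-to-end conservation audit.
    assert counts["simulated"] >= counts["merged"] >= counts["kept"]
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
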