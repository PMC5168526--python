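"""Dual-source stream ingestion, deduplication, and ID-based reconciliation.

Two collection streams see overlapping but different slices of the same tweet
population: a prospective (search-API-like) stream and a retrospective
(firehose-like) stream, the latter treated as the gold standard.  Records are
matched by their unique tweet ID; a record matches only if it is present in
both streams *and* its language field agrees (a user-side language change
between the two collection passes makes the streams disagree and excludes the
record).  The :class:`MergeReport` keeps the full accounting, including
per-cause exclusion counts when a ground-truth match map from
:func:`vaxsent.corpus.simulate_dual_sources` is available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import HPV_KEYWORDS, TweetRecord, record_from_dict
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "EXCLUSION_REASONS",
    "KeywordQuery",
    "MergeReport",
    "ReadResult",
    "read_tweet_stream",
    "dedupe_by_id",
    "merge_sources",
    "filter_language",
    "match_keywords",
]

EXCLUSION_REASONS = ("deleted", "language_flip", "coverage_gap", "no_keyword", "unexplained")


@dataclass(frozen=True)
class KeywordQuery:
    """The ordered keyword list used to collect (and re-match) tweets."""

    keywords: tuple[str, ...] = HPV_KEYWORDS
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ConfigError("keyword list must be nonempty")
        if len(set(self.keywords)) != len(self.keywords):
            raise ConfigError("duplicate keywords are forbidden")


@dataclass
class ReadResult:
    """Records loaded from a JSONL stream plus the malformed-line count."""

    records: list[TweetRecord]
    n_malformed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class MergeReport:
    """Accounting of the ID merge (matched / excluded per side, by cause)."""

    n_prospective: int
    n_retrospective: int
    n_matched: int
    exclusion_reason_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded_prospective(self) -> int:
        return self.n_prospective - self.n_matched

    @property
    def n_excluded_retrospective(self) -> int:
        return self.n_retrospective - self.n_matched

    @property
    def pct_retained_prospective(self) -> float:
        return 100.0 * self.n_matched / self.n_prospective if self.n_prospective else 0.0

    @property
    def pct_retained_retrospective(self) -> float:
        return 100.0 * self.n_matched / self.n_retrospective if self.n_retrospective else 0.0

    @property
    def pct_excluded_prospective(self) -> float:
        return 100.0 - self.pct_retained_prospective if self.n_prospective else 0.0

    @property
    def pct_excluded_retrospective(self) -> float:
        return 100.0 - self.pct_retained_retrospective if self.n_retrospective else 0.0

    def to_dict(self) -> dict:
        return {
            "n_prospective": self.n_prospective,
            "n_retrospective": self.n_retrospective,
            "n_matched": self.n_matched,
            "n_excluded_prospective": self.n_excluded_prospective,
            "n_excluded_retrospective": self.n_excluded_retrospective,
            "pct_retained_prospective": self.pct_retained_prospective,
            "pct_retained_retrospective": self.pct_retained_retrospective,
            "pct_excluded_prospective": self.pct_excluded_prospective,
            "pct_excluded_retrospective": self.pct_excluded_retrospective,
            "exclusion_reason_counts": dict(self.exclusion_reason_counts),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def read_tweet_stream(path) -> ReadResult:
    """Load a JSONL tweet stream; malformed lines are counted, not fatal.

    Raises :class:`DataError` if more than half of the nonempty lines are
    malformed, and propagates OSError for unreadable paths.
    """
    records: list[TweetRecord] = []
    n_bad = 0
    n_lines = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            n_lines += 1
            try:
                records.append(record_from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                n_bad += 1
    if n_lines and n_bad * 2 > n_lines:
        raise DataError(
            f"{path}: {n_bad}/{n_lines} malformed lines; not a tweet JSONL stream"
        )
    if n_bad:
        logger.warning("%s: skipped %d malformed line(s)", path, n_bad)
    return ReadResult(records=records, n_malformed=n_bad)


def dedupe_by_id(records: Iterable[TweetRecord]) -> list[TweetRecord]:
    """One record per tweet_id, keeping the first occurrence."""
    seen: set[int] = set()
    out: list[TweetRecord] = []
    for rec in records:
        if rec.tweet_id not in seen:
            seen.add(rec.tweet_id)
            out.append(rec)
    return out


def merge_sources(
    prospective: Sequence[TweetRecord],
    retrospective: Sequence[TweetRecord],
    match_map: dict[int, str] | None = None,
) -> tuple[list[TweetRecord], MergeReport]:
    """Inner-join two deduplicated streams on tweet ID (and language).

    The merged records carry the retrospective metadata (the gold-standard
    stream, captured later and closer to final retweet/follower values).
    ``exclusion_reason_counts`` counts each excluded tweet ID once; without a
    ground-truth match map, one-sided IDs are attributed heuristically
    (prospective-only -> deleted, retrospective-only -> coverage_gap) and
    language mismatches are observed directly.
    """
    p_by_id = {r.tweet_id: r for r in prospective}
    r_by_id = {r.tweet_id: r for r in retrospective}
    if len(p_by_id) != len(prospective) or len(r_by_id) != len(retrospective):
        raise DataError("merge_sources requires deduplicated streams")

    common = p_by_id.keys() & r_by_id.keys()
    lang_mismatch = {i for i in common if p_by_id[i].language != r_by_id[i].language}
    matched_ids = common - lang_mismatch

    merged = [r for r in retrospective if r.tweet_id in matched_ids]

    reasons: dict[str, int] = {k: 0 for k in EXCLUSION_REASONS}
    p_only = p_by_id.keys() - r_by_id.keys()
    r_only = r_by_id.keys() - p_by_id.keys()
    for tid in p_only:
        reason = match_map.get(tid, "unexplained") if match_map else "deleted"
        reasons[reason if reason in reasons else "unexplained"] += 1
    for tid in r_only:
        reason = match_map.get(tid, "unexplained") if match_map else "coverage_gap"
        reasons[reason if reason in reasons else "unexplained"] += 1
    reasons["language_flip"] += len(lang_mismatch)
    reasons = {k: v for k, v in reasons.items() if v}

    report = MergeReport(
        n_prospective=len(prospective),
        n_retrospective=len(retrospective),
        n_matched=len(matched_ids),
        exclusion_reason_counts=reasons,
    )
    # Conservation is structural; assert it on every run.
    assert report.n_matched == report.n_prospective - report.n_excluded_prospective
    assert report.n_matched == report.n_retrospective - report.n_excluded_retrospective
    return merged, report


def filter_language(records: Iterable[TweetRecord], language: str = "en") -> list[TweetRecord]:
    """Keep records whose language code matches; log the removed count."""
    records = list(records)
    kept = [r for r in records if r.language == language]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_language: removed %d non-%s tweet(s)", removed, language)
    return kept


def match_keywords(text: str, query: KeywordQuery | None = None) -> set[str]:
    """Keywords whose raw-substring match succeeds on the text.

    Matching is plain substring (case-insensitive unless the query says
    otherwise) with ``#`` taken literally, so any text matching
    ``"HPV vaccine"`` necessarily also matches ``"HPV"``.
    """
    query = query or KeywordQuery()
    hay = text if query.case_sensitive else text.casefold()
    out = set()
    for kw in query.keywords:
        needle = kw if query.case_sensitive else kw.casefold()
        if needle and needle in hay:
            out.add(kw)
    return out
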