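"""Keyword-word association: which words are over-represented in the tweets
matching a keyword, relative to the whole corpus.

For a keyword ``k`` let the subset be every tweet whose text matches ``k``.
For each token ``t``,

    p_subset(t)  = count of t in the subset / total tokens in the subset
    p_corpus(t)  = count of t in the corpus / total tokens in the corpus
    score(t)     = p_subset(t) / p_corpus(t)

Tokens are lowercased unigrams plus adjacent bigrams (multi-word phrases are
often the informative units); hashtags keep their ``#``, mentions their
``@``, and URLs collapse to a single ``<url>`` token.  No stop-word list is
applied.  Entries are ranked by score descending, ties broken by token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import log
from typing import Iterable, Sequence

import pandas as pd

from .corpus import TweetRecord
from .merge import KeywordQuery, match_keywords

__all__ = [
    "tokenize",
    "token_stream",
    "AssociationEntry",
    "AssociationTable",
    "association_scores",
    "top_terms",
]

_URL_RE = re.compile(r"https?://\S+")
_TOKEN_RE = re.compile(r"[#@]?[\w']+")
_URL_SENTINEL = "urlsentinel0"


def tokenize(text: str) -> list[str]:
    """Lowercased tokens; URLs collapse to ``<url>``, ``#``/``@`` retained."""
    text = _URL_RE.sub(f" {_URL_SENTINEL} ", text.lower())
    tokens = _TOKEN_RE.findall(text)
    return ["<url>" if t == _URL_SENTINEL else t for t in tokens]


def token_stream(text: str, include_bigrams: bool = True) -> list[str]:
    """Unigrams plus (optionally) adjacent space-joined bigrams."""
    unigrams = tokenize(text)
    if not include_bigrams:
        return unigrams
    bigrams = [f"{a} {b}" for a, b in zip(unigrams, unigrams[1:])]
    return unigrams + bigrams


@dataclass(frozen=True)
class AssociationEntry:
    token: str
    p_subset: float
    p_corpus: float
    score: float

    @property
    def log_score(self) -> float:
        return log(self.score) if self.score > 0 else float("-inf")


@dataclass
class AssociationTable:
    keyword: str
    entries: list[AssociationEntry]
    subset_word_count: int
    corpus_word_count: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "token": e.token,
                    "p_subset": e.p_subset,
                    "p_corpus": e.p_corpus,
                    "score": e.score,
                    "log_score": e.log_score,
                }
                for e in self.entries
            ]
        )


def _text_of(item) -> str:
    return item.text if isinstance(item, TweetRecord) else str(item)


def association_scores(
    corpus: Sequence,
    keyword: str,
    query: KeywordQuery | None = None,
    min_count: int = 5,
    include_bigrams: bool = True,
) -> AssociationTable:
    """Score every token with subset count >= ``min_count`` for one keyword.

    ``corpus`` may hold :class:`TweetRecord` objects or plain strings.  An
    empty subset yields an empty table (subset_word_count 0) as the signal.
    The default ``min_count`` of 5 suppresses hapax artifacts.
    """
    query = query or KeywordQuery()
    if keyword not in query.keywords:
        raise ValueError(f"keyword {keyword!r} is not among the configured queries")

    corpus_counts: dict[str, int] = {}
    subset_counts: dict[str, int] = {}
    corpus_total = 0
    subset_total = 0
    for item in corpus:
        text = _text_of(item)
        tokens = token_stream(text, include_bigrams=include_bigrams)
        in_subset = keyword in match_keywords(text, query)
        corpus_total += len(tokens)
        if in_subset:
            subset_total += len(tokens)
        for t in tokens:
            corpus_counts[t] = corpus_counts.get(t, 0) + 1
            if in_subset:
                subset_counts[t] = subset_counts.get(t, 0) + 1

    entries = []
    for t, c_sub in subset_counts.items():
        if c_sub < min_count:
            continue
        c_cor = corpus_counts[t]
        p_sub = c_sub / subset_total
        p_cor = c_cor / corpus_total
        # Integer products keep mathematically tied scores exactly tied
        # (e.g. all subset-exclusive tokens score corpus_total/subset_total).
        score = (c_sub * corpus_total) / (c_cor * subset_total)
        entries.append(AssociationEntry(t, p_sub, p_cor, score))
    entries.sort(key=lambda e: (-e.score, e.token))
    return AssociationTable(
        keyword=keyword,
        entries=entries,
        subset_word_count=subset_total,
        corpus_word_count=corpus_total,
    )


def top_terms(table: AssociationTable, k: int) -> list[str]:
    """First ``k`` tokens in the table's ranking (fewer if the table is smaller)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [e.token for e in table.entries[:k]]
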