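"""Text featurization for the tweet classifiers.

The design matrix is lowercase unigram counts over a vocabulary fitted on the
labeled tweets only (no leakage from the unlabeled corpus), optionally
followed by four structural features (has_url, has_hashtag, has_mention,
token_count) and an intercept column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assoc import tokenize
from .corpus import TweetRecord
from .errors import ConfigError

__all__ = ["FeatureSpec", "FeatureMatrix", "build_feature_spec", "featurize"]

STRUCTURAL_FEATURES = ("has_url", "has_hashtag", "has_mention", "token_count")


@dataclass(frozen=True)
class FeatureSpec:
    """Deterministic text -> row mapping. Out-of-vocabulary tokens are ignored."""

    vocabulary: tuple[str, ...]
    include_structural: bool = True
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if len(self.vocabulary) == 0:
            raise ConfigError("vocabulary must be nonempty")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ConfigError("vocabulary tokens must be distinct")

    @property
    def n_features(self) -> int:
        return (
            len(self.vocabulary)
            + (len(STRUCTURAL_FEATURES) if self.include_structural else 0)
            + (1 if self.include_intercept else 0)
        )

    @property
    def feature_names(self) -> tuple[str, ...]:
        names = list(self.vocabulary)
        if self.include_structural:
            names.extend(STRUCTURAL_FEATURES)
        if self.include_intercept:
            names.append("intercept")
        return tuple(names)

    def to_dict(self) -> dict:
        return {
            "vocabulary": list(self.vocabulary),
            "include_structural": self.include_structural,
            "include_intercept": self.include_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(
            vocabulary=tuple(d["vocabulary"]),
            include_structural=bool(d["include_structural"]),
            include_intercept=bool(d["include_intercept"]),
        )


@dataclass
class FeatureMatrix:
    X: np.ndarray
    row_ids: np.ndarray
    feature_names: tuple[str, ...]


def _text_and_id(item, default_id: int) -> tuple[str, int]:
    if isinstance(item, TweetRecord):
        return item.text, item.tweet_id
    return str(item), default_id


def build_feature_spec(
    labeled_items: Sequence,
    vocab_size: int = 500,
    include_structural: bool = True,
    include_intercept: bool = True,
) -> FeatureSpec:
    """Fit the vocabulary: top ``vocab_size`` tokens of the labeled set by
    frequency (ties broken alphabetically for determinism)."""
    counts: Counter[str] = Counter()
    for i, item in enumerate(labeled_items):
        text, _ = _text_and_id(item, i)
        counts.update(tokenize(text))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    vocab = tuple(t for t, _ in ranked[:vocab_size])
    if not vocab:
        raise ConfigError("no tokens found while fitting the vocabulary")
    return FeatureSpec(
        vocabulary=vocab,
        include_structural=include_structural,
        include_intercept=include_intercept,
    )


def marker_feature_spec() -> FeatureSpec:
    """Compact vocabulary of the generator's codebook-marker tokens only.

    Useful for experiments on fully synthetic corpora: with fully
    label-specific vocabulary the numeric code is an exact linear function of
    these counts, so a well-determined least-squares fit recovers it exactly.
    """
    from .corpus import (
        prevention_marker_tokens,
        sentiment_marker_tokens,
        side_effect_marker_tokens,
    )

    vocab: list[str] = []
    for c in (1, 2, 3, 4):
        vocab.extend(sentiment_marker_tokens(c))
    vocab.extend(side_effect_marker_tokens())
    vocab.extend(prevention_marker_tokens())
    return FeatureSpec(
        vocabulary=tuple(vocab), include_structural=False, include_intercept=False
    )


def featurize(items: Sequence, spec: FeatureSpec) -> FeatureMatrix:
    """Token-count design matrix for tweets (or raw strings)."""
    index = {t: j for j, t in enumerate(spec.vocabulary)}
    V = len(spec.vocabulary)
    n = len(items)
    X = np.zeros((n, spec.n_features), dtype=float)
    row_ids = np.zeros(n, dtype=np.int64)
    for i, item in enumerate(items):
        text, tid = _text_and_id(item, i)
        row_ids[i] = tid
        tokens = tokenize(text)
        for t in tokens:
            j = index.get(t)
            if j is not None:
                X[i, j] += 1.0
        col = V
        if spec.include_structural:
            X[i, col + 0] = float(any(t == "<url>" for t in tokens))
            X[i, col + 1] = float(any(t.startswith("#") for t in tokens))
            X[i, col + 2] = float(any(t.startswith("@") for t in tokens))
            X[i, col + 3] = float(len(tokens))
            col += 4
        if spec.include_intercept:
            X[i, col] = 1.0
    return FeatureMatrix(X=X, row_ids=row_ids, feature_names=spec.feature_names)
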