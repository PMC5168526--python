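"""Synthetic HPV-vaccine tweet corpora with planted label structure.

Real vaccine-sentiment surveillance corpora cannot be redistributed, so this
module generates labeled stand-ins with the statistical structure the rest of
the pipeline assumes: a 10-keyword HPV vocabulary, a 4-class vaccine-sentiment
label (positive / negative / neutral / no mention) plus binary side-effect and
prevention labels with sentiment-conditional rates, right-skewed (log-normal)
follower counts, heavy-tailed retweet counts, hashtags / mentions / URLs, and
snowflake-style monotone tweet IDs.  ``simulate_dual_sources`` degrades a
corpus into the two imperfect "collection stream" views (a prospective
search-API-like stream and a retrospective firehose-like stream) that the
merge stage reconciles, recording the ground-truth exclusion cause per tweet.

Every draw flows from a single :class:`numpy.random.Generator`, so identical
parameters and seed reproduce a byte-identical JSONL corpus.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError

__all__ = [
    "HPV_KEYWORDS",
    "STUDY_START",
    "STUDY_END",
    "CorpusParams",
    "SourceViewParams",
    "TweetRecord",
    "simulate_corpus",
    "simulate_dual_sources",
    "keyword_marker_token",
    "sentiment_marker_tokens",
    "side_effect_marker_tokens",
    "prevention_marker_tokens",
    "write_jsonl",
    "record_to_dict",
    "record_from_dict",
    "export_labels_csv",
]

#: The ten keyword queries used to collect HPV-vaccination tweets.
HPV_KEYWORDS: tuple[str, ...] = (
    "HPV",
    "#HPV",
    "HPV vaccine",
    "#HPVvaccine",
    "HPV shot",
    "#hpvshot",
    "Gardasil",
    "#Gardasil",
    "Cervarix",
    "#Cervarix",
)

#: Study window: one year of collection.
STUDY_START = dt.datetime(2014, 8, 1, tzinfo=dt.timezone.utc)
STUDY_END = dt.datetime(2015, 8, 1, tzinfo=dt.timezone.utc)

SENTIMENT_CODES = {"positive": 1, "negative": 2, "neutral": 3, "no_mention": 4}
BINARY_CODES = {"absent": 1, "present": 2}

# Default label shares and sentiment-conditional content rates.  These follow
# the published cross-tabulation of a year-long English-language HPV-vaccine
# tweet corpus (see vaxsent.reference): sentiment shares 38.99 / 25.31 /
# 12.98 / 22.72 %, side-effect mentions concentrated in negative tweets,
# prevention mentions in positive and neutral tweets, and per-sentiment
# link / hashtag / mention rates.
DEFAULT_SENTIMENT_PROBS = (0.3899, 0.2531, 0.1298, 0.2272)
DEFAULT_P_SIDE_EFFECTS = (0.1714, 0.4644, 0.1508, 0.0596)
DEFAULT_P_PREVENTION = (0.2709, 0.1154, 0.2579, 0.0730)
DEFAULT_P_LINK = (0.7666, 0.7048, 0.7526, 0.6116)
DEFAULT_P_HASHTAG = (0.4860, 0.4398, 0.4337, 0.4078)
DEFAULT_P_MENTION = (0.5910, 0.6352, 0.5041, 0.5405)
#: Keyword sampling weights; the plain-"HPV" family carries most of the mass
#: so that ~85-90% of texts contain the substring "HPV".
DEFAULT_KEYWORD_WEIGHTS = (0.55, 0.08, 0.12, 0.04, 0.03, 0.02, 0.08, 0.03, 0.03, 0.02)

_N_BACKGROUND = 200
_BACKGROUND_TOKENS = tuple(f"w{k:03d}" for k in range(_N_BACKGROUND))
_HASHTAG_POOL = tuple(f"#h{k}" for k in range(20))
_MENTION_POOL = tuple(f"@u{k}" for k in range(50))
_BASE36 = "0123456789abcdefghijklmnopqrstuvwxyz"


def _slug(keyword: str) -> str:
    return re.sub(r"[^a-z0-9]", "", keyword.lower())


def keyword_marker_token(index: int) -> str:
    """Planted marker hashtag for keyword ``HPV_KEYWORDS[index]``.

    Markers are named ``#a{index}{slug}``.  Tokens that occur *only* inside a
    keyword's tweet subset all attain the same (maximal) association score,
    and ties rank lexicographically; the ``#a`` prefix plus list-order index
    makes each keyword's own marker sort ahead of organic hashtags, of the
    keyword strings themselves, and of markers of keywords whose text embeds
    this keyword (nested keywords always come later in ``HPV_KEYWORDS``).
    """
    return f"#a{index}{_slug(HPV_KEYWORDS[index])}"


def sentiment_marker_tokens(code: int) -> tuple[str, ...]:
    """Vocabulary pool signalling sentiment class ``code`` (1..4)."""
    return tuple(f"s{code}m{j}" for j in range(5))


def side_effect_marker_tokens() -> tuple[str, ...]:
    return tuple(f"sefx{j}" for j in range(5))


def prevention_marker_tokens() -> tuple[str, ...]:
    return tuple(f"prevx{j}" for j in range(5))


def _check_prob_vector(name: str, p: Sequence[float], length: int) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.shape != (length,):
        raise ConfigError(f"{name} must have length {length}, got shape {arr.shape}")
    if (arr < 0).any() or (arr > 1).any():
        raise ConfigError(f"{name} entries must lie in [0, 1]")
    return arr


def _check_simplex(name: str, p: Sequence[float], length: int) -> np.ndarray:
    arr = _check_prob_vector(name, p, length)
    if not math.isclose(arr.sum(), 1.0, abs_tol=1e-9):
        raise ConfigError(f"{name} must sum to 1, got {arr.sum()!r}")
    return arr


@dataclass(frozen=True)
class CorpusParams:
    """Parameters of the synthetic corpus generator.

    ``sentiment_probs`` is the marginal distribution over the four sentiment
    codes; the ``p_*_given_sentiment`` vectors are conditional rates indexed
    by sentiment code - 1.  ``marker_strength`` in [0, 1] interpolates between
    label-free vocabulary (0: classifiers cannot beat chance) and fully
    label-specific vocabulary (1: classes are separable from text alone).
    """

    n_tweets: int
    seed: int
    n_users: int | None = None
    sentiment_probs: tuple[float, ...] = DEFAULT_SENTIMENT_PROBS
    p_side_effects_given_sentiment: tuple[float, ...] = DEFAULT_P_SIDE_EFFECTS
    p_prevention_given_sentiment: tuple[float, ...] = DEFAULT_P_PREVENTION
    p_link_given_sentiment: tuple[float, ...] = DEFAULT_P_LINK
    p_hashtag_given_sentiment: tuple[float, ...] = DEFAULT_P_HASHTAG
    p_mention_given_sentiment: tuple[float, ...] = DEFAULT_P_MENTION
    follower_lognormal_mu: float = 6.1
    follower_lognormal_sigma: float = 1.5
    retweet_tail_param: float = 1.2
    keyword_weights: tuple[float, ...] = DEFAULT_KEYWORD_WEIGHTS
    marker_strength: float = 0.5
    user_zipf_exponent: float = 1.2

    def __post_init__(self) -> None:
        if self.n_tweets < 0:
            raise ConfigError("n_tweets must be nonnegative")
        if self.n_users is not None and self.n_users < 1:
            raise ConfigError("n_users must be positive")
        _check_simplex("sentiment_probs", self.sentiment_probs, 4)
        _check_prob_vector(
            "p_side_effects_given_sentiment", self.p_side_effects_given_sentiment, 4
        )
        _check_prob_vector(
            "p_prevention_given_sentiment", self.p_prevention_given_sentiment, 4
        )
        _check_prob_vector("p_link_given_sentiment", self.p_link_given_sentiment, 4)
        _check_prob_vector(
            "p_hashtag_given_sentiment", self.p_hashtag_given_sentiment, 4
        )
        _check_prob_vector(
            "p_mention_given_sentiment", self.p_mention_given_sentiment, 4
        )
        _check_simplex("keyword_weights", self.keyword_weights, len(HPV_KEYWORDS))
        if not 0.0 <= self.marker_strength <= 1.0:
            raise ConfigError("marker_strength must lie in [0, 1]")
        if self.retweet_tail_param <= 0:
            raise ConfigError("retweet_tail_param must be > 0")

    @property
    def effective_n_users(self) -> int:
        """Users default to ~n_tweets / 2.5 so the mean tweets-per-user > 1."""
        if self.n_users is not None:
            return self.n_users
        return max(1, round(self.n_tweets / 2.5))


@dataclass(frozen=True)
class SourceViewParams:
    """Degradations separating the two collection streams from the truth.

    ``p_delete``: tweets deleted before the retrospective pull (present only
    in the prospective stream).  ``gap_windows``: date intervals the
    prospective collector missed (tweets present only retrospectively).
    ``p_language_flip``: user language preference changed between collections,
    so the prospective copy carries a different language code.
    """

    p_delete: float = 0.0
    p_language_flip: float = 0.0
    gap_windows: tuple[tuple[dt.datetime, dt.datetime], ...] = ()
    seed: int = 0
    flip_language_to: str = "es"

    def __post_init__(self) -> None:
        for name in ("p_delete", "p_language_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for start, end in self.gap_windows:
            if start >= end:
                raise ConfigError("gap window start must precede end")
            if start < STUDY_START or end > STUDY_END:
                raise ConfigError("gap windows must lie within the study window")


@dataclass(slots=True)
class TweetRecord:
    """One tweet with metadata and (for synthetic corpora) latent labels."""

    tweet_id: int
    user_id: int = 0
    timestamp: dt.datetime = STUDY_START
    language: str = "en"
    text: str = ""
    hashtags: list[str] = field(default_factory=list)
    mentions: list[str] = field(default_factory=list)
    urls: list[str] = field(default_factory=list)
    retweet_count: int = 0
    follower_count: int = 0
    latent_sentiment: int | None = None
    latent_side_effects: int | None = None
    latent_prevention: int | None = None


def record_to_dict(rec: TweetRecord) -> dict:
    d = {
        "tweet_id": rec.tweet_id,
        "user_id": rec.user_id,
        "timestamp": rec.timestamp.strftime("%Y-%m-%dT%H:%M:%S+00:00"),
        "language": rec.language,
        "text": rec.text,
        "hashtags": list(rec.hashtags),
        "mentions": list(rec.mentions),
        "urls": list(rec.urls),
        "retweet_count": rec.retweet_count,
        "follower_count": rec.follower_count,
    }
    if rec.latent_sentiment is not None:
        d["latent"] = {
            "sentiment": rec.latent_sentiment,
            "side_effects": rec.latent_side_effects,
            "prevention": rec.latent_prevention,
        }
    return d


def record_from_dict(d: dict) -> TweetRecord:
    latent = d.get("latent") or {}
    ts = dt.datetime.fromisoformat(d["timestamp"])
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=dt.timezone.utc)
    return TweetRecord(
        tweet_id=int(d["tweet_id"]),
        user_id=int(d.get("user_id", 0)),
        timestamp=ts,
        language=str(d.get("language", "en")),
        text=str(d.get("text", "")),
        hashtags=list(d.get("hashtags", [])),
        mentions=list(d.get("mentions", [])),
        urls=list(d.get("urls", [])),
        retweet_count=int(d.get("retweet_count", 0)),
        follower_count=int(d.get("follower_count", 0)),
        latent_sentiment=latent.get("sentiment"),
        latent_side_effects=latent.get("side_effects"),
        latent_prevention=latent.get("prevention"),
    )


def write_jsonl(records: Iterable[TweetRecord], path) -> int:
    """Write one tweet per line, UTF-8; returns the number of lines."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec), ensure_ascii=False, sort_keys=False))
            fh.write("\n")
            n += 1
    return n


def export_labels_csv(records: Iterable[TweetRecord], path, coder_id: str = "synthetic") -> int:
    """Export latent labels as a hand-coded-style CSV (tweet_id, coder_id, codes)."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tweet_id", "coder_id", "sentiment", "side_effects", "prevention"])
        for rec in records:
            if rec.latent_sentiment is None:
                continue
            writer.writerow(
                [rec.tweet_id, coder_id, rec.latent_sentiment,
                 rec.latent_side_effects, rec.latent_prevention]
            )
            n += 1
    return n


def _snowflake_id(offset_ms: int, sequence: int) -> int:
    # Monotone 64-bit IDs: millisecond offset in the high bits, sequence low.
    return (offset_ms << 22) | (sequence & 0x3FFFFF)


def _base36(n: int) -> str:
    if n == 0:
        return "0"
    out = []
    while n:
        n, r = divmod(n, 36)
        out.append(_BASE36[r])
    return "".join(reversed(out))


def simulate_corpus(params: CorpusParams) -> list[TweetRecord]:
    """Generate ``params.n_tweets`` labeled tweets.

    Each text contains its sampled keyword; with probability
    ``marker_strength`` it also carries the keyword's planted marker hashtag.
    Label-conditional vocabulary: a fixed number of slots per variable are
    filled from the label's marker pool with probability ``marker_strength``
    and from the shared background vocabulary otherwise, so the number of
    tokens never leaks the label and ``marker_strength = 0`` yields
    label-independent text.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_tweets
    if n == 0:
        return []

    n_users = params.effective_n_users
    sent_probs = np.asarray(params.sentiment_probs, dtype=float)
    sentiments = rng.choice(4, size=n, p=sent_probs / sent_probs.sum()) + 1
    p_se = np.asarray(params.p_side_effects_given_sentiment)[sentiments - 1]
    p_pr = np.asarray(params.p_prevention_given_sentiment)[sentiments - 1]
    side_effects = (rng.random(n) < p_se).astype(int) + 1
    prevention = (rng.random(n) < p_pr).astype(int) + 1
    has_link = rng.random(n) < np.asarray(params.p_link_given_sentiment)[sentiments - 1]
    has_hash = rng.random(n) < np.asarray(params.p_hashtag_given_sentiment)[sentiments - 1]
    has_ment = rng.random(n) < np.asarray(params.p_mention_given_sentiment)[sentiments - 1]

    kw_weights = np.asarray(params.keyword_weights, dtype=float)
    kw_idx = rng.choice(len(HPV_KEYWORDS), size=n, p=kw_weights / kw_weights.sum())

    # Users follow a Zipf popularity law; follower counts are per-user
    # log-normal draws so the mean far exceeds the median.
    ranks = np.arange(1, n_users + 1, dtype=float)
    user_w = ranks ** (-params.user_zipf_exponent)
    user_w /= user_w.sum()
    user_ids = rng.choice(n_users, size=n, p=user_w)
    followers_by_user = np.floor(
        rng.lognormal(params.follower_lognormal_mu, params.follower_lognormal_sigma, n_users)
    ).astype(np.int64)
    retweets = np.floor(rng.pareto(params.retweet_tail_param, n) * 2.0).astype(np.int64)

    start_s = int(STUDY_START.timestamp())
    end_s = int(STUDY_END.timestamp())
    ts_seconds = np.sort(rng.integers(start_s, end_s, size=n))

    bg_weights = 1.0 / np.arange(1, _N_BACKGROUND + 1) ** 1.1
    bg_weights /= bg_weights.sum()
    # Pre-draw background token indices in bulk for speed.
    bg_draws = rng.choice(_N_BACKGROUND, size=12 * n, p=bg_weights)
    bg_pos = 0

    strength = params.marker_strength
    sefx_pool = side_effect_marker_tokens()
    prevx_pool = prevention_marker_tokens()
    sent_pools = {c: sentiment_marker_tokens(c) for c in (1, 2, 3, 4)}

    u_marker = rng.random(n)
    u_slots = rng.random((n, 6))
    # Two marker slots per codebook variable, drawn without replacement so a
    # tweet never spends both slots on the same topical token.
    first = rng.integers(0, 5, size=(n, 3))
    second = (first + rng.integers(1, 5, size=(n, 3))) % 5
    slot_pool_idx = np.empty((n, 6), dtype=np.int64)
    slot_pool_idx[:, 0::2] = first
    slot_pool_idx[:, 1::2] = second
    n_filler = rng.integers(2, 6, size=n)
    hash_choice = rng.integers(0, len(_HASHTAG_POOL), size=n)
    ment_choice = rng.integers(0, len(_MENTION_POOL), size=n)

    records: list[TweetRecord] = []
    for i in range(n):
        s = int(sentiments[i])
        parts: list[str] = []
        if has_ment[i]:
            parts.append(_MENTION_POOL[ment_choice[i]])
        parts.append(HPV_KEYWORDS[kw_idx[i]])
        if u_marker[i] < strength:
            parts.append(keyword_marker_token(int(kw_idx[i])))
        # Two slots per codebook variable; pool vs background per slot.
        pools = (
            sent_pools[s], sent_pools[s],
            sefx_pool if side_effects[i] == 2 else None,
            sefx_pool if side_effects[i] == 2 else None,
            prevx_pool if prevention[i] == 2 else None,
            prevx_pool if prevention[i] == 2 else None,
        )
        for j, pool in enumerate(pools):
            if pool is not None and u_slots[i, j] < strength:
                parts.append(pool[slot_pool_idx[i, j]])
            else:
                parts.append(_BACKGROUND_TOKENS[bg_draws[bg_pos]])
                bg_pos += 1
        for _ in range(int(n_filler[i])):
            parts.append(_BACKGROUND_TOKENS[bg_draws[bg_pos]])
            bg_pos += 1
        if has_hash[i]:
            parts.append(_HASHTAG_POOL[hash_choice[i]])
        if has_link[i]:
            parts.append(f"http://t.co/{_base36(i + 1)}")

        text = " ".join(parts)
        while len(text) > 140 and int(n_filler[i]) > 0:
            # Drop filler tokens (they sit just before hashtag/link) until it fits.
            del parts[-(1 + int(has_hash[i]) + int(has_link[i]))]
            n_filler[i] -= 1
            text = " ".join(parts)

        hashtags = [p for p in parts if p.startswith("#")]
        mentions = [p for p in parts if p.startswith("@")]
        urls = [p for p in parts if p.startswith("http")]

        offset_ms = (int(ts_seconds[i]) - start_s) * 1000
        records.append(
            TweetRecord(
                tweet_id=_snowflake_id(offset_ms, i),
                user_id=int(user_ids[i]),
                timestamp=dt.datetime.fromtimestamp(int(ts_seconds[i]), tz=dt.timezone.utc),
                language="en",
                text=text,
                hashtags=hashtags,
                mentions=mentions,
                urls=urls,
                retweet_count=int(retweets[i]),
                follower_count=int(followers_by_user[user_ids[i]]),
                latent_sentiment=s,
                latent_side_effects=int(side_effects[i]),
                latent_prevention=int(prevention[i]),
            )
        )
    return records


def simulate_dual_sources(
    corpus: Sequence[TweetRecord], params: SourceViewParams
) -> tuple[list[TweetRecord], list[TweetRecord], dict[int, str]]:
    """Degrade a corpus into (prospective, retrospective) views.

    Returns the two streams plus a ground-truth match map
    ``tweet_id -> reason`` with reasons ``matched`` / ``deleted`` /
    ``coverage_gap`` / ``language_flip``.  Deleted tweets are missing from the
    retrospective stream; gap-window tweets are missing from the prospective
    stream; language-flipped tweets appear in both but with a different
    language code prospectively.  When a tweet qualifies for several causes
    the precedence is deleted > coverage_gap > language_flip.
    """
    if len(corpus) == 0:
        raise ConfigError("simulate_dual_sources requires a nonempty corpus")
    rng = np.random.default_rng(params.seed)
    n = len(corpus)
    deleted = rng.random(n) < params.p_delete
    flipped = rng.random(n) < params.p_language_flip

    def in_gap(ts: dt.datetime) -> bool:
        return any(start <= ts < end for start, end in params.gap_windows)

    prospective: list[TweetRecord] = []
    retrospective: list[TweetRecord] = []
    match_map: dict[int, str] = {}
    for i, rec in enumerate(corpus):
        gap = in_gap(rec.timestamp)
        if deleted[i]:
            reason = "deleted"
        elif gap:
            reason = "coverage_gap"
        elif flipped[i]:
            reason = "language_flip"
        else:
            reason = "matched"
        match_map[rec.tweet_id] = reason
        if not deleted[i]:
            retrospective.append(rec)
        if not gap:
            if flipped[i]:
                prospective.append(
                    dataclasses.replace(rec, language=params.flip_language_to)
                )
            else:
                prospective.append(rec)
    return prospective, retrospective, match_map
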