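"""Sentiment cross-tabulation, keyword shares, and the statistical tests.

`summarize_by_sentiment` builds, per sentiment class and overall: tweet
counts and shares, distinct users and tweets per user, follower mean/median
(per user, deduplicated within class using the user's maximum observed
value), link / hashtag / mention / prevention / side-effect counts, and
retweet mean/median.  Percentages are always derived from the stored counts
at output time, never stored independently.

Group comparisons use the Pearson chi-square test for counts and categorical
variables, one-way ANOVA for continuous variables, and Mood's nonparametric
median test (a chi-square on the groups x {above, <= } grand-median table)
for medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UndefinedStatisticError
from .merge import KeywordQuery, match_keywords

__all__ = [
    "CLASS_NAMES",
    "ClassStats",
    "SentimentSummary",
    "summarize_by_sentiment",
    "keyword_share",
    "TestResult",
    "chi_square",
    "anova_oneway",
    "median_test",
]

CLASS_NAMES = ("positive", "negative", "neutral", "no_mention")
_CODE_TO_NAME = {i + 1: name for i, name in enumerate(CLASS_NAMES)}


@dataclass
class ClassStats:
    """Raw counts and direct measurements for one sentiment class (or total)."""

    n_tweets: int
    n_users: int
    n_link: int
    n_hashtag: int
    n_mention: int
    n_prevention: int
    n_side_effects: int
    mean_followers: float
    median_followers: float
    mean_retweets: float
    median_retweets: float

    @property
    def mean_tweets_per_user(self) -> float:
        return self.n_tweets / self.n_users if self.n_users else 0.0


@dataclass
class SentimentSummary:
    classes: dict[str, ClassStats]
    total: ClassStats

    def _cell(self, name: str) -> ClassStats:
        return self.total if name == "total" else self.classes[name]

    def pct_of_sample(self, name: str) -> float:
        return 100.0 * self.classes[name].n_tweets / self.total.n_tweets

    def pct(self, name: str, count_field: str) -> float:
        cell = self._cell(name)
        if cell.n_tweets == 0:
            return 0.0
        return 100.0 * getattr(cell, count_field) / cell.n_tweets

    def pct_link(self, name: str) -> float:
        return self.pct(name, "n_link")

    def pct_hashtag(self, name: str) -> float:
        return self.pct(name, "n_hashtag")

    def pct_mention(self, name: str) -> float:
        return self.pct(name, "n_mention")

    def pct_prevention(self, name: str) -> float:
        return self.pct(name, "n_prevention")

    def pct_side_effects(self, name: str) -> float:
        return self.pct(name, "n_side_effects")

    @classmethod
    def from_counts(cls, counts: Mapping) -> "SentimentSummary":
        """Build a summary from a stored count fixture (see vaxsent.reference)."""
        classes = {
            name: ClassStats(**counts["classes"][name]) for name in CLASS_NAMES
        }
        total = ClassStats(
            n_tweets=counts["n_total"],
            n_users=counts["n_users_total"],
            **counts["totals"],
        )
        summary = cls(classes=classes, total=total)
        if sum(c.n_tweets for c in classes.values()) != total.n_tweets:
            raise DataError("class tweet counts do not sum to the total")
        return summary

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in (*CLASS_NAMES, "total"):
            cell = self._cell(name)
            rows.append(
                {
                    "sentiment": name,
                    "n_tweets": cell.n_tweets,
                    "pct_of_sample": self.pct_of_sample(name) if name != "total" else 100.0,
                    "n_users": cell.n_users,
                    "mean_tweets_per_user": cell.mean_tweets_per_user,
                    "mean_followers": cell.mean_followers,
                    "median_followers": cell.median_followers,
                    "n_link": cell.n_link,
                    "pct_link": self.pct_link(name),
                    "n_hashtag": cell.n_hashtag,
                    "pct_hashtag": self.pct_hashtag(name),
                    "n_mention": cell.n_mention,
                    "pct_mention": self.pct_mention(name),
                    "n_prevention": cell.n_prevention,
                    "pct_prevention": self.pct_prevention(name),
                    "n_side_effects": cell.n_side_effects,
                    "pct_side_effects": self.pct_side_effects(name),
                    "mean_retweets": cell.mean_retweets,
                    "median_retweets": cell.median_retweets,
                }
            )
        return pd.DataFrame(rows)


def _class_stats(g: pd.DataFrame) -> ClassStats:
    followers = g.groupby("user_id")["follower_count"].max()
    return ClassStats(
        n_tweets=int(len(g)),
        n_users=int(g["user_id"].nunique()),
        n_link=int(g["has_link"].sum()),
        n_hashtag=int(g["has_hashtag"].sum()),
        n_mention=int(g["has_mention"].sum()),
        n_prevention=int((g["prevention"] == 2).sum()),
        n_side_effects=int((g["side_effects"] == 2).sum()),
        mean_followers=float(followers.mean()),
        median_followers=float(followers.median()),
        mean_retweets=float(g["retweet_count"].mean()),
        median_retweets=float(g["retweet_count"].median()),
    )


def summarize_by_sentiment(df: pd.DataFrame) -> SentimentSummary:
    """Cross-tabulate a classified corpus by sentiment.

    ``df`` needs columns: sentiment (codes 1-4), user_id, follower_count,
    retweet_count, has_link, has_hashtag, has_mention, prevention,
    side_effects (codes 1/2).  Discards must already be removed.
    """
    required = {
        "sentiment", "user_id", "follower_count", "retweet_count",
        "has_link", "has_hashtag", "has_mention", "prevention", "side_effects",
    }
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"summary frame is missing columns {sorted(missing)}")
    if len(df) == 0:
        raise DataError("empty corpus: nothing to summarize")

    classes = {}
    for code, name in _CODE_TO_NAME.items():
        g = df[df["sentiment"] == code]
        if len(g) == 0:
            classes[name] = ClassStats(0, 0, 0, 0, 0, 0, 0, float("nan"),
                                       float("nan"), float("nan"), float("nan"))
        else:
            classes[name] = _class_stats(g)
    total = _class_stats(df)
    return SentimentSummary(classes=classes, total=total)


def keyword_share(
    records: Sequence, query: KeywordQuery | None = None
) -> dict[str, tuple[int, float]]:
    """Per-keyword (count, percent of corpus); categories are not mutually
    exclusive — a tweet counts for every keyword its text matches."""
    query = query or KeywordQuery()
    if len(records) == 0:
        raise DataError("empty corpus")
    counts = {kw: 0 for kw in query.keywords}
    for rec in records:
        text = rec.text if hasattr(rec, "text") else str(rec)
        for kw in match_keywords(text, query):
            counts[kw] += 1
    n = len(records)
    return {kw: (c, 100.0 * c / n) for kw, c in counts.items()}


# ---------------------------------------------------------------------------
# statistical tests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | tuple[int, int]
    p_value: float
    test_name: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df if isinstance(self.df, int) else list(self.df),
            "p_value": self.p_value,
            "test_name": self.test_name,
        }


def chi_square(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise DataError("chi_square expects a 2-D count table")
    if (obs < 0).any():
        raise DataError("counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DataError("zero marginal in contingency table")
    expected = np.outer(rows, cols) / obs.sum()
    resid = np.abs(obs - expected)
    if correction and obs.shape == (2, 2):
        resid = np.maximum(resid - 0.5, 0.0)  # Yates
    stat = float((resid**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return TestResult(
        statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)), test_name="chi_square"
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA F test from between/within sums of squares."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2 or any(len(g) < 1 for g in gs):
        raise DataError("ANOVA needs >= 2 nonempty groups")
    n = sum(len(g) for g in gs)
    if n <= k:
        raise DataError("ANOVA needs total n > number of groups")
    grand = np.concatenate(gs).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n - k
    ms_within = ss_within / df2
    ms_between = ss_between / df1
    if ms_within == 0.0:
        if ms_between == 0.0:
            raise UndefinedStatisticError("no variance anywhere: F undefined")
        return TestResult(float("inf"), (df1, df2), 0.0, "anova_F")
    f = float(ms_between / ms_within)
    return TestResult(
        statistic=f, df=(df1, df2), p_value=float(stats.f.sf(f, df1, df2)), test_name="anova_F"
    )


def median_test_table(groups: Sequence[Sequence[float]]) -> np.ndarray:
    """Groups x {above, <=} counts around the pooled grand median (ties to
    the <=-median cell, Mood's convention)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(gs)
    grand = np.median(pooled)
    return np.array(
        [[int((g > grand).sum()), int((g <= grand).sum())] for g in gs], dtype=float
    )


def median_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Mood's median test: chi-square on the above/<= grand-median table."""
    if len(groups) < 2:
        raise DataError("median test needs >= 2 groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        raise UndefinedStatisticError("all values identical: median test undefined")
    table = median_test_table(groups)
    result = chi_square(table)
    return TestResult(
        statistic=result.statistic,
        df=result.df,
        p_value=result.p_value,
        test_name="median_test",
    )
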