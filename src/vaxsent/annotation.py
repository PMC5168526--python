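"""Codebook schema, hand-coded label loading, and interrater reliability.

The codebook has one multiclass variable — vaccine sentiment (1 positive,
2 negative, 3 neutral, 4 no mention of the vaccine although HPV is mentioned)
— and two binary variables, side_effects and prevention, coded 1 = absent,
2 = present.  Zero is never a valid code for any variable: that convention is
what makes the downstream rounded-zero discard rule meaningful.

Interrater reliability is Krippendorff's alpha for nominal data (appropriate
for 5 coders and categorical codes), with raw mean pairwise percent agreement
reported alongside for transparency.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedStatisticError

__all__ = [
    "CodebookVariable",
    "CodebookSchema",
    "LabeledTweet",
    "default_schema",
    "load_labels",
    "krippendorff_alpha",
    "percent_agreement",
    "interrater_reliability",
]


@dataclass(frozen=True)
class CodebookVariable:
    name: str
    kind: str  # "multiclass" | "binary"
    codes: Mapping[str, int]

    def __post_init__(self) -> None:
        vals = sorted(self.codes.values())
        if vals != list(range(1, len(vals) + 1)):
            raise DataError(
                f"variable {self.name!r}: codes must be distinct consecutive "
                f"integers starting at 1 (0 is never valid), got {vals}"
            )
        if self.kind == "binary" and len(vals) != 2:
            raise DataError(f"binary variable {self.name!r} must have 2 codes")

    @property
    def valid_codes(self) -> frozenset[int]:
        return frozenset(self.codes.values())

    @property
    def max_code(self) -> int:
        return max(self.codes.values())


@dataclass(frozen=True)
class CodebookSchema:
    variables: tuple[CodebookVariable, ...]

    def __getitem__(self, name: str) -> CodebookVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def to_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "kind": v.kind, "codes": dict(v.codes)}
                for v in self.variables
            ]
        }


def default_schema() -> CodebookSchema:
    """Sentiment (4 codes) plus the two binary content variables."""
    return CodebookSchema(
        variables=(
            CodebookVariable(
                "sentiment",
                "multiclass",
                {"positive": 1, "negative": 2, "neutral": 3, "no_mention": 4},
            ),
            CodebookVariable("side_effects", "binary", {"absent": 1, "present": 2}),
            CodebookVariable("prevention", "binary", {"absent": 1, "present": 2}),
        )
    )


@dataclass(frozen=True)
class LabeledTweet:
    tweet_id: int
    coder_id: str
    sentiment: int
    side_effects: int
    prevention: int

    def code(self, variable: str) -> int:
        return getattr(self, variable)


def load_labels(path, schema: CodebookSchema | None = None) -> list[LabeledTweet]:
    """Load a hand-coded label CSV and validate every code against the schema.

    Expected columns: tweet_id, coder_id, sentiment, side_effects, prevention.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path, dtype={"coder_id": str})
    required = ["tweet_id", "coder_id", *schema.names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"label file {path} is missing columns {missing}")
    labels: list[LabeledTweet] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        values = {}
        for var in schema.variables:
            code = getattr(row, var.name)
            try:
                code = int(code)
            except (TypeError, ValueError):
                code = None
            if code not in var.valid_codes:
                raise DataError(
                    f"{path} row {row_number}: invalid code {getattr(row, var.name)!r} "
                    f"for variable {var.name!r}"
                )
            values[var.name] = code
        labels.append(
            LabeledTweet(tweet_id=int(row.tweet_id), coder_id=str(row.coder_id), **values)
        )
    return labels


def krippendorff_alpha(values: Sequence[Sequence[object]]) -> float:
    """Krippendorff's alpha for nominal data.

    ``values`` is a coders x items matrix; ``None`` / NaN marks a missing
    rating.  Items rated by fewer than two coders are dropped.  Raises
    :class:`UndefinedStatisticError` when only one category is observed
    (expected disagreement is zero, so agreement beyond chance is undefined).
    """
    arr = [list(row) for row in values]
    if not arr:
        raise DataError("empty reliability matrix")
    n_items = len(arr[0])
    if any(len(row) != n_items for row in arr):
        raise DataError("ragged reliability matrix")

    def is_missing(v) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v))

    # Coincidence matrix over observed categories.
    coincidence: dict[tuple[object, object], float] = defaultdict(float)
    category_totals: dict[object, float] = defaultdict(float)
    for u in range(n_items):
        ratings = [row[u] for row in arr if not is_missing(row[u])]
        m = len(ratings)
        if m < 2:
            continue
        for i, a in enumerate(ratings):
            for j, b in enumerate(ratings):
                if i != j:
                    coincidence[(a, b)] += 1.0 / (m - 1)
    for (a, _b), w in coincidence.items():
        category_totals[a] += w
    n_total = sum(category_totals.values())
    if n_total == 0:
        raise DataError("no item was rated by two or more coders")
    if len(category_totals) < 2:
        raise UndefinedStatisticError(
            "only one category observed; chance-corrected agreement undefined"
        )
    d_observed = sum(w for (a, b), w in coincidence.items() if a != b) / n_total
    d_expected = sum(
        na * nb for a, na in category_totals.items() for b, nb in category_totals.items() if a != b
    ) / (n_total * (n_total - 1))
    return 1.0 - d_observed / d_expected


def percent_agreement(values: Sequence[Sequence[object]]) -> float:
    """Mean over items of the fraction of agreeing coder pairs."""
    arr = [list(row) for row in values]
    n_items = len(arr[0]) if arr else 0
    fractions = []
    for u in range(n_items):
        ratings = [row[u] for row in arr if row[u] is not None]
        m = len(ratings)
        if m < 2:
            continue
        agree = sum(
            1 for i in range(m) for j in range(i + 1, m) if ratings[i] == ratings[j]
        )
        fractions.append(agree / (m * (m - 1) / 2))
    if not fractions:
        raise DataError("no item was rated by two or more coders")
    return float(np.mean(fractions))


def _reliability_matrix(
    labels: Iterable[LabeledTweet], variable: str
) -> list[list[object]]:
    by_coder: dict[str, dict[int, int]] = defaultdict(dict)
    items: set[int] = set()
    for lab in labels:
        by_coder[lab.coder_id][lab.tweet_id] = lab.code(variable)
        items.add(lab.tweet_id)
    item_order = sorted(items)
    return [
        [by_coder[c].get(tid) for tid in item_order] for c in sorted(by_coder)
    ]


def interrater_reliability(
    labels: Sequence[LabeledTweet], schema: CodebookSchema | None = None
) -> dict[str, dict[str, float]]:
    """Per-variable Krippendorff alpha (+ percent agreement) across coders.

    Requires at least two coders sharing at least one tweet.  A variable with
    a single observed category yields ``alpha = None`` (undefined) rather
    than an exception, so one degenerate variable does not hide the others.
    """
    schema = schema or default_schema()
    coders = {lab.coder_id for lab in labels}
    if len(coders) < 2:
        raise DataError("interrater reliability requires >= 2 coders")
    out: dict[str, dict[str, float]] = {}
    for var in schema.names:
        matrix = _reliability_matrix(labels, var)
        try:
            alpha = krippendorff_alpha(matrix)
        except UndefinedStatisticError:
            alpha = None
        out[var] = {"alpha": alpha, "percent_agreement": percent_agreement(matrix)}
    return out
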