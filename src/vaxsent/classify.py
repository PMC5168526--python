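"""The two classifier families, leave-one-out evaluation, and corpus coding.

Binary codebook variables (coded {1 absent, 2 present}) are classified by a
linear model fit with the Moore-Penrose pseudoinverse, w = X+ y — the
minimum-norm least-squares regression of the numeric codes on the features.
The multiclass sentiment variable uses a greedy binary CART decision tree
minimizing Gini impurity.

Evaluation is leave-one-out: train on n-1 tweets, score the held-out tweet,
pool all n held-out scores, and compute AUC (binary; probability a random
positive outscores a random negative, half credit for ties) or the error
fraction (multiclass).  For full-column-rank designs the linear held-out
prediction has the closed form (yhat_i - h_ii y_i) / (1 - h_ii) with h_ii the
leverage of the full fit, which this module uses as a fast path; the explicit
retrain loop remains available and is verified against it.

Applying trained models to the full corpus follows the discard rules: linear
scores are rounded half-away-from-zero to integer codes; no variable admits
the code 0, so a rounded zero on any variable discards the tweet; codes
beyond the variable's range clamp to the nearest valid code; and a tweet
whose certainty is not above the threshold (default 70%) is likewise
discarded, each discard carrying its attributed cause.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .annotation import CodebookSchema, default_schema
from .errors import ConfigError, DataError, UndefinedStatisticError
from .features import FeatureMatrix, FeatureSpec, featurize

__all__ = [
    "LinearModel",
    "TreeNode",
    "TreeModel",
    "EvalResult",
    "ClassifiedTweet",
    "DiscardReport",
    "fit_linear_pinv",
    "predict_linear",
    "fit_tree",
    "predict_tree",
    "compute_auc",
    "multiclass_ovr_auc",
    "loo_linear_scores",
    "loo_evaluate",
    "learning_curve",
    "round_half_away",
    "assign_linear_codes",
    "certainty_linear",
    "classify_corpus",
]


# ---------------------------------------------------------------------------
# linear (pseudoinverse) classifier


@dataclass
class LinearModel:
    w: np.ndarray
    target: str = ""
    feature_spec: FeatureSpec | None = None

    def to_dict(self) -> dict:
        d = {"kind": "linear", "target": self.target, "w": self.w.tolist()}
        if self.feature_spec is not None:
            d["feature_spec"] = self.feature_spec.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        spec = d.get("feature_spec")
        return cls(
            w=np.asarray(d["w"], dtype=float),
            target=d.get("target", ""),
            feature_spec=FeatureSpec.from_dict(spec) if spec else None,
        )


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def fit_linear_pinv(X, y, target: str = "") -> LinearModel:
    """Minimum-norm least-squares weights w = X+ y."""
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=float)
    if Xa.ndim != 2 or Xa.shape[0] != ya.shape[0]:
        raise DataError("X and y have incompatible shapes")
    if not np.any(Xa):
        warnings.warn("all-zero design matrix; returning zero weights")
        return LinearModel(w=np.zeros(Xa.shape[1]), target=target)
    w = np.linalg.pinv(Xa) @ ya
    return LinearModel(w=w, target=target)


def predict_linear(model: LinearModel, X) -> np.ndarray:
    Xa = _as_array(X)
    if Xa.shape[1] != model.w.shape[0]:
        raise DataError(
            f"feature dimension mismatch: X has {Xa.shape[1]}, model expects {model.w.shape[0]}"
        )
    return Xa @ model.w


# ---------------------------------------------------------------------------
# CART decision tree (Gini)


@dataclass
class TreeNode:
    dist: np.ndarray  # class distribution at the node (sums to 1)
    n: int
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"dist": self.dist.tolist(), "n": self.n}
        if not self.is_leaf:
            d.update(
                feature=self.feature,
                threshold=self.threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(dist=np.asarray(d["dist"], dtype=float), n=int(d["n"]))
        if "feature" in d:
            node.feature = int(d["feature"])
            node.threshold = float(d["threshold"])
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class TreeModel:
    root: TreeNode
    classes: tuple[int, ...]
    max_depth: int
    min_leaf: int
    target: str = ""

    def to_dict(self) -> dict:
        return {
            "kind": "tree",
            "target": self.target,
            "classes": list(self.classes),
            "max_depth": self.max_depth,
            "min_leaf": self.min_leaf,
            "root": self.root.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        return cls(
            root=TreeNode.from_dict(d["root"]),
            classes=tuple(int(c) for c in d["classes"]),
            max_depth=int(d["max_depth"]),
            min_leaf=int(d["min_leaf"]),
            target=d.get("target", ""),
        )


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _best_split(X: np.ndarray, Y: np.ndarray, min_leaf: int):
    """Exhaustive search over features and thresholds for the split minimizing
    the weighted child Gini impurity.  Ties resolve to the first candidate in
    (feature, threshold) scan order.  Returns None if no admissible split
    improves on the parent impurity."""
    n, p = X.shape
    parent = _gini(Y.sum(axis=0))
    best = None  # (weighted_gini, feature, threshold)
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = Y[order]
        cum = np.cumsum(ys, axis=0)
        total = cum[-1]
        for i in range(min_leaf - 1, n - min_leaf):
            if xs[i] == xs[i + 1]:
                continue
            left = cum[i]
            right = total - left
            nl = i + 1
            nr = n - nl
            wg = (nl * _gini(left) + nr * _gini(right)) / n
            if best is None or wg < best[0] - 1e-12:
                best = (wg, j, float((xs[i] + xs[i + 1]) / 2.0))
    if best is None or best[0] >= parent - 1e-12:
        return None
    return best[1], best[2]


def _grow(X, Y, depth, max_depth, min_leaf) -> TreeNode:
    counts = Y.sum(axis=0)
    n = int(counts.sum())
    dist = counts / n if n else counts
    node = TreeNode(dist=dist, n=n)
    if depth >= max_depth or n < 2 * min_leaf or np.count_nonzero(counts) < 2:
        return node
    split = _best_split(X, Y, min_leaf)
    if split is None:
        return node
    j, thr = split
    mask = X[:, j] <= thr
    node.feature = j
    node.threshold = thr
    node.left = _grow(X[mask], Y[mask], depth + 1, max_depth, min_leaf)
    node.right = _grow(X[~mask], Y[~mask], depth + 1, max_depth, min_leaf)
    return node


def fit_tree(X, y, max_depth: int = 8, min_leaf: int = 5, target: str = "") -> TreeModel:
    """Greedy binary CART minimizing Gini impurity; leaves store class
    distributions.  With n < 2*min_leaf the tree is a single leaf."""
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=int)
    classes = tuple(sorted(np.unique(ya).tolist()))
    Y = np.stack([(ya == c).astype(float) for c in classes], axis=1)
    root = _grow(Xa, Y, 0, max_depth, min_leaf)
    return TreeModel(root=root, classes=classes, max_depth=max_depth, min_leaf=min_leaf, target=target)


def predict_tree(model: TreeModel, X) -> tuple[np.ndarray, np.ndarray]:
    """(assigned class, certainty = leaf majority fraction) per row.

    Class is the argmax of the leaf distribution with ties broken toward the
    lowest code.
    """
    Xa = _as_array(X)
    codes = np.zeros(Xa.shape[0], dtype=int)
    certainty = np.zeros(Xa.shape[0], dtype=float)
    classes = np.asarray(model.classes)
    for i in range(Xa.shape[0]):
        node = model.root
        while not node.is_leaf:
            node = node.left if Xa[i, node.feature] <= node.threshold else node.right
        k = int(np.argmax(node.dist))  # argmax returns the first (lowest) code on ties
        codes[i] = classes[k]
        certainty[i] = float(node.dist[k])
    return codes, certainty


def predict_tree_proba(model: TreeModel, X) -> np.ndarray:
    """Leaf class distribution per row (columns follow ``model.classes``)."""
    Xa = _as_array(X)
    out = np.zeros((Xa.shape[0], len(model.classes)))
    for i in range(Xa.shape[0]):
        node = model.root
        while not node.is_leaf:
            node = node.left if Xa[i, node.feature] <= node.threshold else node.right
        out[i] = node.dist
    return out


# ---------------------------------------------------------------------------
# AUC and leave-one-out evaluation


def compute_auc(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie) over all positive-negative pairs.

    The higher code is the positive class.  Computed from midranks, which is
    exactly the pairwise concordance.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise UndefinedStatisticError("AUC undefined: only one class present")
    if classes.size > 2:
        raise DataError("compute_auc expects binary labels")
    pos = y == classes.max()
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    ranks = rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def multiclass_ovr_auc(proba: np.ndarray, labels, classes: Sequence[int]) -> float:
    """Macro-averaged one-vs-rest AUC from class probabilities.

    The only way to summarize a multiclass variable with a single AUC: each
    class's probability column is scored against the class-vs-rest
    indicator, and the per-class AUCs are averaged.  Classes absent from
    ``labels`` are skipped.
    """
    y = np.asarray(labels)
    aucs = []
    for k, c in enumerate(classes):
        ind = (y == c).astype(int) + 1  # {1 rest, 2 class c}
        if np.unique(ind).size < 2:
            continue
        aucs.append(compute_auc(proba[:, k], ind))
    if not aucs:
        raise UndefinedStatisticError("no class with both members present")
    return float(np.mean(aucs))


@dataclass
class EvalResult:
    n: int
    auc: float | None = None
    error_fraction: float | None = None
    curve: list[tuple[int, float, float]] = field(default_factory=list)


def loo_linear_scores(X, y, method: str = "auto") -> np.ndarray:
    """Pooled held-out linear scores, one per row.

    ``method='hat'`` uses the closed-form identity
    (yhat_i - h_ii y_i) / (1 - h_ii), valid for full-column-rank designs;
    ``'refit'`` retrains n times; ``'auto'`` picks the fast path when it is
    exact (full rank and all leverages < 1).
    """
    Xa = _as_array(X)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n < 3:
        raise DataError("leave-one-out needs n >= 3")

    if method in ("auto", "hat"):
        pinv = np.linalg.pinv(Xa)
        h = np.einsum("ij,ji->i", Xa, pinv)
        full_rank = np.linalg.matrix_rank(Xa) == p
        ok = full_rank and np.all(h < 1.0 - 1e-10)
        if method == "hat" and not ok:
            raise DataError("hat-matrix shortcut requires full column rank and leverages < 1")
        if ok:
            yhat = Xa @ (pinv @ ya)
            return (yhat - h * ya) / (1.0 - h)
        # fall through to refit

    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        model = fit_linear_pinv(Xa[mask], ya[mask])
        scores[i] = Xa[i] @ model.w
    return scores


def loo_evaluate(
    X,
    y,
    model_kind: str = "linear",
    max_depth: int = 8,
    min_leaf: int = 5,
    method: str = "auto",
) -> EvalResult:
    """Leave-one-out evaluation with pooled held-out predictions.

    Binary targets (linear models) report AUC; multiclass targets (trees)
    report the error fraction.
    """
    Xa = _as_array(X)
    ya = np.asarray(y)
    n = Xa.shape[0]
    if n < 3:
        raise DataError("leave-one-out needs n >= 3")
    if np.unique(ya).size < 2:
        raise UndefinedStatisticError("leave-one-out undefined for single-class labels")

    if model_kind == "linear":
        scores = loo_linear_scores(Xa, ya.astype(float), method=method)
        return EvalResult(n=n, auc=compute_auc(scores, ya))
    if model_kind == "tree":
        idx = np.arange(n)
        preds = np.empty(n, dtype=int)
        for i in range(n):
            mask = idx != i
            model = fit_tree(Xa[mask], ya[mask], max_depth=max_depth, min_leaf=min_leaf)
            preds[i] = predict_tree(model, Xa[i : i + 1])[0][0]
        return EvalResult(n=n, error_fraction=float(np.mean(preds != ya)))
    raise ConfigError(f"unknown model_kind {model_kind!r}")


def learning_curve(
    X,
    y,
    sizes: Sequence[int],
    reps: int = 5,
    seed: int = 0,
    model_kind: str = "linear",
    **kwargs,
) -> list[tuple[int, float, float]]:
    """Mean and SD of the LOO metric over ``reps`` random subsamples per size.

    Subsamples are drawn without replacement and redrawn (up to 100 times)
    when they contain a single class.  Sizes below 4 are skipped with a
    warning.  With ``reps=1`` and ``m = n`` this equals ``loo_evaluate`` on
    the full data.
    """
    Xa = _as_array(X)
    ya = np.asarray(y)
    n = Xa.shape[0]
    if max(sizes) > n:
        raise ConfigError("learning-curve sizes cannot exceed n")
    rng = np.random.default_rng(seed)
    points: list[tuple[int, float, float]] = []
    for m in sorted(sizes):
        if m < 4:
            warnings.warn(f"learning_curve: skipping size {m} < 4")
            continue
        vals = []
        for _ in range(reps):
            for _attempt in range(100):
                take = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
                if np.unique(ya[take]).size >= 2:
                    break
            res = loo_evaluate(Xa[take], ya[take], model_kind=model_kind, **kwargs)
            vals.append(res.auc if res.auc is not None else res.error_fraction)
        points.append((m, float(np.mean(vals)), float(np.std(vals))))
    return points


# ---------------------------------------------------------------------------
# full-corpus classification with the discard rules


def round_half_away(x) -> np.ndarray:
    """Round to the nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def assign_linear_codes(scores, max_code: int) -> np.ndarray:
    """Rounded codes; 0 means "discard"; nonzero out-of-range codes clamp to
    the nearest valid code in [1, max_code]."""
    rounded = round_half_away(scores)
    out = rounded.copy()
    nonzero = rounded != 0
    out[nonzero] = np.clip(rounded[nonzero], 1, max_code)
    out[~nonzero] = 0
    return out


def certainty_linear(scores) -> np.ndarray:
    """1 - 2|score - round(score)|, clipped to [0, 1]: confidence that the
    rounded code is the intended one."""
    s = np.asarray(scores, dtype=float)
    return np.clip(1.0 - 2.0 * np.abs(s - round_half_away(s)), 0.0, 1.0)


@dataclass
class ClassifiedTweet:
    tweet_id: int
    codes: dict[str, int]
    certainty: dict[str, float]
    discarded: bool
    causes: tuple[str, ...]


@dataclass
class DiscardReport:
    n_total: int
    n_kept: int
    n_discarded: int
    cause_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "n_discarded": self.n_discarded,
            "cause_counts": dict(self.cause_counts),
        }


def classify_corpus(
    models: dict[str, LinearModel | TreeModel],
    corpus: Sequence,
    spec: FeatureSpec,
    schema: CodebookSchema | None = None,
    certainty_threshold: float = 0.70,
) -> tuple[list[ClassifiedTweet], DiscardReport]:
    """Apply per-variable models to a corpus with the discard rules.

    A tweet is discarded when any variable rounds to the invalid code 0
    (cause ``rounded_zero:<variable>``) or is not classified with certainty
    above ``certainty_threshold`` (cause ``low_certainty:<variable>``).
    """
    schema = schema or default_schema()
    fm = featurize(corpus, spec)
    n = fm.X.shape[0]
    codes: dict[str, np.ndarray] = {}
    cert: dict[str, np.ndarray] = {}
    zero: dict[str, np.ndarray] = {}
    for var, model in models.items():
        max_code = schema[var].max_code
        if isinstance(model, TreeModel):
            c, q = predict_tree(model, fm.X)
            codes[var], cert[var] = c, q
            zero[var] = np.zeros(n, dtype=bool)
        else:
            scores = predict_linear(model, fm.X)
            assigned = assign_linear_codes(scores, max_code)
            codes[var] = assigned
            cert[var] = certainty_linear(scores)
            zero[var] = assigned == 0

    results: list[ClassifiedTweet] = []
    cause_counts: dict[str, int] = {}
    n_discarded = 0
    for i in range(n):
        causes = []
        for var in models:
            if zero[var][i]:
                causes.append(f"rounded_zero:{var}")
            if cert[var][i] <= certainty_threshold:
                causes.append(f"low_certainty:{var}")
        discarded = bool(causes)
        n_discarded += discarded
        for c in causes:
            cause_counts[c] = cause_counts.get(c, 0) + 1
        results.append(
            ClassifiedTweet(
                tweet_id=int(fm.row_ids[i]),
                codes={v: int(codes[v][i]) for v in models},
                certainty={v: float(cert[v][i]) for v in models},
                discarded=discarded,
                causes=tuple(causes),
            )
        )
    report = DiscardReport(
        n_total=n,
        n_kept=n - n_discarded,
        n_discarded=n_discarded,
        cause_counts=cause_counts,
    )
    return results, report


def save_models(models: dict[str, LinearModel | TreeModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh)


def load_models(path) -> dict[str, LinearModel | TreeModel]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    out: dict[str, LinearModel | TreeModel] = {}
    for k, d in raw.items():
        out[k] = TreeModel.from_dict(d) if d.get("kind") == "tree" else LinearModel.from_dict(d)
    return out
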