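"""Featurization, the two classifier families, AUC, and leave-one-out."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from vaxsent.classify import (
    assign_linear_codes,
    certainty_linear,
    classify_corpus,
    compute_auc,
    fit_linear_pinv,
    fit_tree,
    learning_curve,
    loo_evaluate,
    loo_linear_scores,
    predict_linear,
    predict_tree,
    round_half_away,
)
from vaxsent.corpus import CorpusParams, simulate_corpus
from vaxsent.errors import ConfigError, DataError, UndefinedStatisticError
from vaxsent.features import (
    FeatureSpec,
    build_feature_spec,
    featurize,
    marker_feature_spec,
)


class TestFeaturize:
    SPEC = FeatureSpec(vocabulary=("hpv", "vaccine", "safe", "shot", "cancer"))

    def test_empty_text_all_zero_token_features(self):
        fm = featurize([""], self.SPEC)
        assert fm.X.shape == (1, 5 + 4 + 1)
        assert np.all(fm.X[0, :9] == 0)  # tokens + structural all zero
        assert fm.X[0, -1] == 1.0  # intercept

    def test_single_vocabulary_token_is_one_hot(self):
        fm = featurize(["vaccine"], self.SPEC)
        assert fm.X[0, :5].tolist() == [0, 1, 0, 0, 0]
        assert fm.X[0, 5:9].tolist() == [0, 0, 0, 1]  # token_count = 1

    def test_counts_match_hand_enumeration(self):
        texts = [
            "HPV vaccine vaccine is safe",
            "the shot the shot the shot",
            "cancer http://t.co/x #tag @user",
        ]
        fm = featurize(texts, self.SPEC)
        expected_counts = np.array(
            [[1, 2, 1, 0, 0], [0, 0, 0, 3, 0], [0, 0, 0, 0, 1]], dtype=float
        )
        assert np.array_equal(fm.X[:, :5], expected_counts)
        # structural: has_url, has_hashtag, has_mention, token_count
        assert fm.X[2, 5:9].tolist() == [1, 1, 1, 4]
        assert fm.X[0, 5:9].tolist() == [0, 0, 0, 5]

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ConfigError):
            FeatureSpec(vocabulary=())

    def test_vocabulary_fitted_on_labeled_data_only(self, separable_corpus):
        spec = build_feature_spec(separable_corpus, vocab_size=50)
        assert len(spec.vocabulary) == 50
        assert len(set(spec.vocabulary)) == 50


class TestLinearPinv:
    def test_identity_design_reproduces_y(self):
        X = np.eye(3)
        y = np.array([1.0, 2.0, 2.0])
        model = fit_linear_pinv(X, y)
        assert model.w == pytest.approx([1, 2, 2])
        assert predict_linear(model, X) == pytest.approx(y)

    def test_zero_targets_give_zero_weights(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        model = fit_linear_pinv(X, np.zeros(5))
        assert model.w == pytest.approx(np.zeros(3), abs=1e-12)

    def test_all_zero_design_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            model = fit_linear_pinv(np.zeros((4, 2)), np.ones(4))
        assert np.all(model.w == 0)

    def test_matches_normal_equations_on_full_rank_system(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.choice([1.0, 2.0], size=6)
        model = fit_linear_pinv(X, y)
        w_ne = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.w == pytest.approx(w_ne, abs=1e-8)
        assert predict_linear(model, X) == pytest.approx(X @ w_ne, abs=1e-8)

    def test_residual_not_beaten_by_random_weights(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.choice([1.0, 2.0], size=30)
        w_star = fit_linear_pinv(X, y).w
        best = np.linalg.norm(X @ w_star - y)
        for _ in range(1000):
            w = rng.normal(scale=2.0, size=5)
            assert np.linalg.norm(X @ w - y) >= best - 1e-9

    def test_dimension_mismatch_rejected(self):
        model = fit_linear_pinv(np.eye(3), np.ones(3))
        with pytest.raises(DataError):
            predict_linear(model, np.ones((2, 4)))


class TestTree:
    def test_pure_labels_single_leaf(self):
        X = np.arange(10.0).reshape(-1, 1)
        model = fit_tree(X, np.full(10, 3))
        assert model.root.is_leaf
        codes, cert = predict_tree(model, X)
        assert np.all(codes == 3) and np.all(cert == 1.0)

    def test_threshold_separable_three_classes_zero_training_error(self):
        X = np.array([[0.0], [1], [2], [10], [11], [12], [20], [21], [22]])
        y = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        model = fit_tree(X, y, min_leaf=1)
        codes, _ = predict_tree(model, X)
        assert np.array_equal(codes, y)

    def test_split_matches_brute_force_oracle(self):
        X = np.array(
            [[0.0, 5.0], [1, 4], [2, 3], [3, 2], [4, 1], [5, 0], [6, 6], [7, 7]]
        )
        y = np.array([1, 1, 2, 2, 3, 3, 3, 1])

        def gini(labels):
            _, c = np.unique(labels, return_counts=True)
            p = c / c.sum()
            return 1 - (p**2).sum()

        best = None
        for j in range(2):
            for thr in np.unique(X[:, j])[:-1]:
                mid = (thr + np.unique(X[:, j])[np.unique(X[:, j]) > thr][0]) / 2
                mask = X[:, j] <= mid
                if mask.sum() == 0 or (~mask).sum() == 0:
                    continue
                wg = (mask.sum() * gini(y[mask]) + (~mask).sum() * gini(y[~mask])) / len(y)
                if best is None or wg < best[0] - 1e-12:
                    best = (wg, j, mid)
        model = fit_tree(X, y, max_depth=1, min_leaf=1)
        assert model.root.feature == best[1]
        assert model.root.threshold == pytest.approx(best[2])

    def test_predictions_match_manual_traversal(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1], [2, 0], [2, 1]])
        y = np.array([1, 1, 2, 2, 3, 3])
        model = fit_tree(X, y, min_leaf=1)

        def walk(node, row):
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            k = int(np.argmax(node.dist))
            return model.classes[k], node.dist[k]

        codes, cert = predict_tree(model, X)
        for i in range(len(X)):
            c, q = walk(model.root, X[i])
            assert codes[i] == c and cert[i] == pytest.approx(q)

    def test_tiny_sample_yields_single_leaf(self):
        model = fit_tree(np.ones((3, 2)), np.array([1, 2, 3]), min_leaf=5)
        assert model.root.is_leaf

    def test_leaf_distributions_sum_to_one(self, separable_corpus):
        spec = build_feature_spec(separable_corpus, vocab_size=60)
        fm = featurize(separable_corpus, spec)
        y = np.array([r.latent_sentiment for r in separable_corpus])
        model = fit_tree(fm.X, y)

        def check(node, depth):
            assert depth <= model.max_depth
            assert node.dist.sum() == pytest.approx(1.0)
            if not node.is_leaf:
                check(node.left, depth + 1)
                check(node.right, depth + 1)

        check(model.root, 0)


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([1, 2, 3, 10, 11], [1, 1, 1, 2, 2]) == 1.0

    def test_all_ties_half(self):
        assert compute_auc([5, 5, 5, 5], [1, 2, 1, 2]) == 0.5

    def test_four_point_example(self):
        # brute force over the 4 positive-negative pairs: 3 concordant,
        # 1 discordant -> 0.75
        assert compute_auc([0.9, 0.8, 0.7, 0.6], [2, 1, 2, 1]) == 0.75

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            compute_auc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 6), st.sampled_from([1, 2])),
            min_size=2,
            max_size=200,
        )
    )
    def test_equals_brute_force_pair_concordance(self, pairs):
        scores = [float(s) for s, _ in pairs]
        labels = [l for _, l in pairs]
        if len(set(labels)) < 2:
            return
        pos = [s for s, l in zip(scores, labels) if l == 2]
        neg = [s for s, l in zip(scores, labels) if l == 1]
        brute = sum(
            (a > b) + (0.5 if a == b else 0.0) for a in pos for b in neg
        ) / (len(pos) * len(neg))
        assert compute_auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=80)
        labels = rng.choice([1, 2], size=80)
        a = compute_auc(scores, labels)
        assert compute_auc(np.exp(3 * scores), labels) == pytest.approx(a)

    def test_agrees_with_sklearn(self, rng):
        scores = rng.normal(size=120)
        labels = rng.choice([1, 2], size=120)
        assert compute_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels == 2, scores)
        )


class TestLeaveOneOut:
    def test_closed_form_identity_vs_explicit_retraining(self, rng):
        """(yhat_i - h_ii y_i)/(1 - h_ii) equals retrained held-out scores."""
        for _ in range(50):
            n = int(rng.integers(8, 30))
            p = int(rng.integers(2, 6))
            X = rng.normal(size=(n, p))
            y = rng.choice([1.0, 2.0], size=n)
            fast = loo_linear_scores(X, y, method="hat")
            slow = loo_linear_scores(X, y, method="refit")
            assert np.max(np.abs(fast - slow)) <= 1e-8

    def test_separable_synthetic_data_gives_auc_one(self, separable_corpus):
        # with fully label-specific vocabulary the code is an exact linear
        # function of the marker counts, so every held-out fit is exact and
        # the ranking is perfect
        spec = marker_feature_spec()
        fm = featurize(separable_corpus, spec)
        y = np.array([r.latent_side_effects for r in separable_corpus], dtype=float)
        assert loo_evaluate(fm.X, y, model_kind="linear").auc == 1.0

    def test_null_labels_give_auc_near_half(self):
        corpus = simulate_corpus(CorpusParams(n_tweets=200, seed=4, marker_strength=0.0))
        spec = build_feature_spec(corpus, vocab_size=50)
        fm = featurize(corpus, spec)
        y = np.array([r.latent_side_effects for r in corpus], dtype=float)
        auc = loo_evaluate(fm.X, y, model_kind="linear").auc
        n1 = int((y == 2).sum())
        n0 = int((y == 1).sum())
        se = np.sqrt((len(y) + 1) / (12 * n1 * n0))
        assert abs(auc - 0.5) < 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            loo_evaluate(np.eye(5), np.ones(5), model_kind="tree")

    def test_tree_loo_error_fraction_low_on_separable_sentiment(self, separable_corpus):
        spec = build_feature_spec(separable_corpus, vocab_size=60)
        fm = featurize(separable_corpus, spec)
        y = np.array([r.latent_sentiment for r in separable_corpus])
        res = loo_evaluate(fm.X, y, model_kind="tree", min_leaf=2)
        assert res.auc is None
        assert res.error_fraction < 0.25


class TestLearningCurve:
    def test_full_size_single_rep_equals_loo(self, separable_corpus):
        spec = build_feature_spec(separable_corpus, vocab_size=100)
        fm = featurize(separable_corpus, spec)
        y = np.array([r.latent_side_effects for r in separable_corpus], dtype=float)
        points = learning_curve(fm.X, y, sizes=[len(y)], reps=1, seed=0)
        assert points[0][1] == loo_evaluate(fm.X, y).auc
        assert points[0][2] == 0.0

    def test_monotone_on_separable_data_and_deterministic(self, separable_corpus):
        spec = marker_feature_spec()
        fm = featurize(separable_corpus, spec)
        y = np.array([r.latent_side_effects for r in separable_corpus], dtype=float)
        a = learning_curve(fm.X, y, sizes=(20, 40, 60), reps=3, seed=7)
        b = learning_curve(fm.X, y, sizes=(20, 40, 60), reps=3, seed=7)
        assert a == b
        means = [m for _, m, _ in a]
        assert all(x <= y_ + 1e-12 for x, y_ in zip(means, means[1:]))
        assert [m for m, _, _ in a] == [20, 40, 60]

    def test_small_sizes_skipped_with_warning(self, separable_corpus):
        spec = build_feature_spec(separable_corpus, vocab_size=50)
        fm = featurize(separable_corpus, spec)
        y = np.array([r.latent_side_effects for r in separable_corpus], dtype=float)
        with pytest.warns(UserWarning):
            points = learning_curve(fm.X, y, sizes=(2, 20), reps=1, seed=0)
        assert [m for m, _, _ in points] == [20]


class TestDiscardRules:
    def test_rounding_half_away_from_zero(self):
        assert round_half_away([0.5, 1.5, -0.5, 2.4, -1.6]).tolist() == [1, 2, -1, 2, -2]

    def test_assign_codes_rounds_discards_and_clamps(self):
        codes = assign_linear_codes(np.array([0.49, 1.51, 3.7, 0.4, 1.2]), max_code=4)
        assert codes.tolist() == [0, 2, 4, 0, 1]
        codes2 = assign_linear_codes(np.array([2.8, -1.2]), max_code=2)
        assert codes2.tolist() == [2, 1]  # clamp both directions, 0 stays discard

    def test_certainty_peaks_at_integers(self):
        assert certainty_linear([1.0, 2.0]).tolist() == [1.0, 1.0]
        assert certainty_linear([1.5]) == pytest.approx([0.0])
        assert certainty_linear([1.9]) == pytest.approx([0.8])

    def test_classify_corpus_attributes_causes(self, separable_corpus):
        spec = build_feature_spec(separable_corpus, vocab_size=200)
        fm = featurize(separable_corpus, spec)
        models = {}
        for var in ("side_effects", "prevention"):
            y = np.array([getattr(r, f"latent_{var}") for r in separable_corpus], float)
            models[var] = fit_linear_pinv(fm.X, y, target=var)
        y_s = np.array([r.latent_sentiment for r in separable_corpus])
        models["sentiment"] = fit_tree(fm.X, y_s, min_leaf=2, target="sentiment")
        classified, report = classify_corpus(models, separable_corpus, spec)
        assert report.n_total == len(separable_corpus)
        assert report.n_kept + report.n_discarded == report.n_total
        for ct in classified:
            zero = any(c.startswith("rounded_zero") for c in ct.causes)
            low = any(c.startswith("low_certainty") for c in ct.causes)
            assert ct.discarded == (zero or low)
            for var in models:
                assert ct.codes[var] != 0 or zero
            if not ct.discarded:
                assert all(q > 0.70 for q in ct.certainty.values())


class TestMulticlassOvrAUC:
    def test_matches_sklearn_macro_ovr(self, rng, separable_corpus):
        from sklearn.metrics import roc_auc_score

        from vaxsent.classify import multiclass_ovr_auc, predict_tree_proba

        spec = build_feature_spec(separable_corpus, vocab_size=60)
        fm = featurize(separable_corpus, spec)
        y = np.array([r.latent_sentiment for r in separable_corpus])
        model = fit_tree(fm.X, y, min_leaf=2)
        proba = predict_tree_proba(model, fm.X)
        ours = multiclass_ovr_auc(proba, y, model.classes)
        # sklearn macro OVR averages over present classes the same way
        ref = np.mean([
            roc_auc_score(y == c, proba[:, k]) for k, c in enumerate(model.classes)
        ])
        assert ours == pytest.approx(ref)

    def test_perfect_probabilities_score_one(self):
        from vaxsent.classify import multiclass_ovr_auc

        y = np.array([1, 2, 3, 1, 2, 3])
        proba = np.eye(3)[y - 1]
        assert multiclass_ovr_auc(proba, y, (1, 2, 3)) == 1.0
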