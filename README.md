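# vaxsent

A tested, reusable pipeline for vaccine-sentiment surveillance on Twitter-style
data ("infoveillance"). It is built around the study design used for
year-long HPV-vaccine monitoring: tweets are collected under 10 keyword
queries ("HPV", "#HPV", "HPV vaccine", "#HPVvaccine", "HPV shot", "#hpvshot",
"Gardasil", "#Gardasil", "Cervarix", "#Cervarix") through two imperfect
channels — a prospective search-API stream and a retrospective firehose pull
— reconciled record-by-record through the unique tweet ID. A hand-coded
subsample trains content classifiers that code the full corpus for vaccine
sentiment (positive / negative / neutral / no mention), side-effect mentions,
and prevention/protection mentions, and the coded corpus is cross-tabulated
and tested for differences by sentiment.

Because real tweet corpora cannot be redistributed, the package ships a
synthetic-corpus generator that emulates the statistical structure such a
corpus exhibits (label-conditional vocabulary and content rates, log-normal
follower counts, heavy-tailed retweets, two degraded source views), so every
stage of the pipeline is exercised end to end with known ground truth.

## The methods at its core

- **Dual-source reconciliation.** Records match when the tweet ID appears in
  both streams and the language field agrees; every exclusion is counted and,
  when ground truth is available, attributed to a cause (deletion, collection
  gap, language flip, no keyword, unexplained).
- **Pseudoinverse linear classifier.** Binary variables coded y ∈ {1, 2}ⁿ are
  regressed on a token-count design matrix X via the Moore-Penrose
  pseudoinverse, w = X⁺y — the minimum-norm least-squares solution. Scores
  Xw are rounded half-away-from-zero to integer codes; since 0 is not a valid
  code for any variable, a rounded 0 discards the tweet, as does certainty
  not above 70% (for linear scores, certainty = 1 − 2|score − round(score)|).
- **CART decision tree.** The 4-class sentiment variable uses greedy binary
  splits minimizing Gini impurity; leaf class distributions supply the
  assigned code and its certainty.
- **Leave-one-out evaluation.** Train on n−1, score the held-out tweet, pool
  all n held-out scores, and compute AUC = P(score₊ > score₋) + ½P(tie)
  (binary) or the error fraction (multiclass). For full-column-rank designs
  the held-out linear prediction has the closed form
  (ŷᵢ − hᵢᵢyᵢ)/(1 − hᵢᵢ) with hᵢᵢ the leverage of the full fit. Learning
  curves report mean ± SD of the LOO metric over random subsamples.
- **Keyword-word association.** For each keyword, every token is scored by
  p_subset / p_corpus, where each probability is the token's count over the
  total token count of the respective set (tweets matching the keyword vs the
  whole corpus).
- **Sentiment analytics.** A cross-tabulation of counts, user aggregates,
  content features, and retweets by sentiment, compared with Pearson
  chi-square tests (counts), one-way ANOVA (means), and Mood's median test
  (medians).

## Worked example

```python
import numpy as np
import vaxsent as v
from vaxsent.features import build_feature_spec, featurize
from vaxsent.classify import loo_evaluate
from vaxsent.assoc import association_scores, top_terms

params = v.CorpusParams(n_tweets=5000, seed=11, marker_strength=0.8)
corpus = v.simulate_corpus(params)
pro, retro, mm = v.simulate_dual_sources(
    corpus, v.SourceViewParams(p_delete=0.05, p_language_flip=0.02, seed=12))
merged, report = v.merge_sources(pro, retro, mm)
print("matched", report.n_matched, "reasons", report.exclusion_reason_counts)
print("retained: %.2f%% / %.2f%%"
      % (report.pct_retained_prospective, report.pct_retained_retrospective))

labeled = corpus[:1470]
spec = build_feature_spec(labeled, vocab_size=300)
fm = featurize(labeled, spec)
y = np.array([r.latent_side_effects for r in labeled], float)
print("side-effects LOO AUC: %.3f" % loo_evaluate(fm.X, y).auc)

table = association_scores(merged, "Gardasil", min_count=5)
print("top Gardasil term:", top_terms(table, 1))
```

prints

```
matched 4640 reasons {'deleted': 278, 'language_flip': 82}
retained: 92.80% / 98.26%
side-effects LOO AUC: 0.990
top Gardasil term: ['#a6gardasil']
```

Of the 5,000 simulated tweets, 278 were deleted before the retrospective
pull and 82 changed language between collections, leaving 4,640 matched
records (92.80% of the prospective and 98.26% of the retrospective stream).
With strongly label-specific vocabulary (`marker_strength=0.8`) the
pseudoinverse classifier reaches a leave-one-out AUC of 0.99 on the
side-effect variable, and the keyword-association ranking recovers the
generator's planted Gardasil marker token as the top associated term.

The same flow is available from the shell:

```sh
vaxsent run-all --config config.toml --out-dir runs/demo
```

which writes the corpus, both source views, the merge report, trained
models, the classified corpus with discard causes, per-keyword association
tables, the sentiment summary, and a manifest with per-stage row counts.

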