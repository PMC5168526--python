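# Methods

This note documents the models, parameters, and design choices behind
`vaxsent`, and what the synthetic-data experiments do and do not establish.

## The surveillance design being modelled

A year of tweets (1 Aug 2014 – 31 Jul 2015) matching 10 HPV-vaccination
keywords is collected twice: prospectively through a rate-limited search API
and retrospectively through a firehose-style complete pull (the gold
standard). The two streams disagree because of tweet deletion, collection
gaps, and user language-preference changes. After reconciling them by tweet
ID, an English-language, keyword-matched corpus is coded — by hand for a
training subsample, then by machine — for three codebook variables:

| variable    | kind       | codes |
|-------------|------------|-------|
| sentiment   | multiclass | 1 positive, 2 negative, 3 neutral, 4 no mention of the vaccine (HPV only) |
| side_effects| binary     | 1 absent, 2 present |
| prevention  | binary     | 1 absent, 2 present |

Zero is deliberately not a valid code anywhere; that convention is what the
rounded-zero discard rule relies on.

## Synthetic corpus generator (`vaxsent.corpus`)

The generator is the package's stand-in for an undistributable corpus. Its
defaults are the study conditions:

- **Sentiment shares** (0.3899, 0.2531, 0.1298, 0.2272) and the
  sentiment-conditional rates of side-effect mentions (0.1714, 0.4644,
  0.1508, 0.0596), prevention mentions (0.2709, 0.1154, 0.2579, 0.0730),
  links, hashtags, and mentions follow the published cross-tabulation
  bundled in `vaxsent/data/reference_counts.json`.
- **Followers** are per-user log-normal, μ = 6.1, σ = 1.5: median
  e^6.1 ≈ 446 matches the published median 443; the mean-to-median ratio
  e^{σ²/2} ≈ 3.1 reproduces the "mean ≫ median" right skew. (The published
  mean of 6569 would require σ ≈ 2.3; the defaults favour the documented
  median and a conservative tail.)
- **Retweets** are floor(2·Pareto(a)) with tail index a = 1.2 — heavy-tailed
  with finite mean, median ~1.
- **Users** receive tweets under a Zipf(1.2) popularity law; the default
  user count is n_tweets/2.5 so tweets-per-user averages ~2.5.
- **Keyword weights** put 0.84 of the mass on the six "HPV"-containing
  queries, so ~85–90% of texts contain the substring "HPV", matching the
  observed dominance of that keyword.
- **Timestamps** are uniform over the study window (their true distribution
  is uncharacterized); tweet IDs are snowflake-style monotone 64-bit
  integers (millisecond offset in the high bits).

Text is a bag of tokens: the sampled keyword, an optional keyword-marker
hashtag, two slots per codebook variable, 2–5 shared background tokens
(Zipf-weighted over 200 types), and optional organic hashtag / mention /
URL. Each variable slot is filled from that label's marker pool with
probability `marker_strength` and from the background vocabulary otherwise,
so slot *count* never leaks the label: at `marker_strength = 0` text is
label-independent (classifiers cannot beat chance), at 1 the classes are
exactly separable. The two slots of a variable draw distinct pool tokens.

Two deliberate, load-bearing naming choices:

- **Keyword markers are hashtags `#a{index}{slug}`.** Any token occurring
  only inside a keyword's subset attains the identical maximal association
  score (total corpus tokens / total subset tokens), and ties rank
  lexicographically. The `#a` prefix sorts markers ahead of organic
  hashtags and the keyword strings themselves, and the list-order index
  sorts a keyword's own marker ahead of markers of nested keywords (any
  keyword whose text embeds another appears later in the canonical list).
  This makes planted-marker rank-1 recovery deterministic rather than
  tie-break-dependent.
- **Association scores are computed as integer-product ratios**
  (c_sub·T_corpus)/(c_corpus·T_subset), so mathematically tied scores are
  exactly tied in floating point.

`simulate_dual_sources` degrades a corpus into the two stream views:
deletion (missing retrospectively), gap windows (missing prospectively),
language flips (present in both, language differs prospectively), with
per-tweet ground-truth cause (precedence: deleted > gap > flip).

## Merge semantics (`vaxsent.merge`)

A record matches when its ID is in both deduplicated streams *and* the
language fields agree; a language mismatch excludes the record from both
sides under the cause `language_flip`. Keyword matching is case-insensitive
raw substring with `#` literal, which yields the containment property that
any text matching "HPV vaccine" also matches "HPV". Duplicates keep the
first occurrence; merged records carry the retrospective metadata (captured
later, closer to final retweet/follower values). The merge report stores
only counts; every percentage is derived on access.

## Annotation reliability (`vaxsent.annotation`)

Interrater reliability is Krippendorff's alpha for nominal data (suited to
5 coders and categorical codes), computed from the coincidence matrix with
items rated by fewer than two coders dropped; mean pairwise percent
agreement is reported alongside. A variable with a single observed category
has zero expected disagreement and reports an undefined (None) alpha rather
than crashing. Note that chance-corrected agreement is *not* monotone under
duplicating a coder — expected disagreement can shift faster than observed
agreement — so only weaker invariants hold (perfect agreement is preserved;
alpha is invariant to consistent relabeling).

## Classifiers and evaluation (`vaxsent.features`, `vaxsent.classify`)

Features are lowercase unigram counts over the top-500 tokens of the
*labeled* set (no vocabulary leakage from the unlabeled corpus; frequency
ties break alphabetically for determinism), plus four structural features
(has_url, has_hashtag, has_mention, token_count) and an intercept. This is
the simplest family compatible with a pseudoinverse classifier at ~1,470
training tweets. `marker_feature_spec()` offers a compact alternative —
the generator's 30 codebook-marker tokens only, no intercept or structural
columns — for experiments where an exact linear relation between counts
and codes is wanted.

- **Linear:** w = X⁺y via `numpy.linalg.pinv` (minimum-norm least squares).
  An all-zero design returns w = 0 with a warning.
- **Tree (sentiment):** greedy binary CART minimizing Gini impurity;
  defaults max_depth 8, min_leaf 5; ties in the split search keep the first
  candidate in (feature, threshold) order; prediction ties break toward the
  lowest code.
- **LOO:** held-out predictions are pooled into one ranking before scoring
  (a single held-out point has no AUC). For the linear model a
  full-column-rank fast path uses the leverage identity
  (ŷᵢ − hᵢᵢyᵢ)/(1 − hᵢᵢ), verified elementwise (≤ 1e-8) against explicit
  retraining; rank-deficient designs fall back to retraining. AUC uses
  midranks (exact pairwise concordance with half-credit ties).
- **Multiclass AUC**, when wanted for a single-number summary, is the
  macro-averaged one-vs-rest AUC over tree leaf probabilities.
- **Discard rules:** linear scores round half-away-from-zero; rounded 0 on
  any variable discards the tweet (`rounded_zero:<var>`); nonzero
  out-of-range codes clamp to the nearest valid code (only the zero case
  mandates discarding). Certainty is 1 − 2|score − round(score)| for linear
  scores and the leaf majority fraction for the tree; certainty not above
  the 0.70 threshold discards (`low_certainty:<var>`). Every discard
  carries its attributed cause(s).

Two regime notes, relevant to interpreting the synthetic experiments. With
the full 500-token vocabulary and only 60 training tweets the design is
wider than it is tall; minimum-norm interpolation then neither guarantees a
perfect ranking on separable data nor a calibrated chance-level ranking on
label-free data. The separability experiment therefore uses
`marker_feature_spec()` (p = 30 < n, the code an exact linear function of
the counts, so every held-out fit is exact and LOO AUC is exactly 1), and
the null experiment uses a 50-token vocabulary (p ≪ n = 200), where the
pooled-LOO AUC is empirically unbiased at 0.5 with spread close to the
binomial pairwise SE.

## Word association (`vaxsent.assoc`)

Tokens are lowercased unigrams plus adjacent bigrams (multi-word phrases
are often the informative units); hashtags keep `#`, mentions keep `@`,
URLs collapse to `<url>`; no stop-word list. For each keyword, tokens with
subset count ≥ min_count (default 5, suppressing hapax artifacts) are
scored by p_subset/p_corpus (log-ratio reported alongside), ranked by score
then token. An empty subset yields an empty table.

## Analytics (`vaxsent.analytics`)

The sentiment summary stores raw counts and direct measurements; every
percentage is recomputed from counts at output time. Per-class follower
statistics deduplicate users within the class, using each user's maximum
observed follower count. Tests: Pearson chi-square (no continuity
correction by default — the intended tables are huge; a Yates flag exists
for small 2×2 tables), one-way ANOVA from sums of squares, and Mood's
median test implemented as a chi-square on the groups × {above, ≤}
grand-median table with ties assigned to the ≤ cell.

The bundled `reference_counts.json` holds only raw counts (tweets, users,
links, hashtags, mentions, prevention and side-effect mentions per
sentiment class, keyword match counts, and the dual-source merge sizes)
plus directly measured means/medians; it is the arithmetic ground truth the
summary stage is validated against, to two decimals.

## Problem sizes

Test and acceptance runs use deliberately compact sizes: 60-tweet separable
and 200-tweet null corpora for LOO behaviour, 5,000 tweets for association
recovery, 50,000 for conditional-rate recovery (3-SE binomial bands), and
100,000 follower draws for the log-normal closed form (10% band). The merge
arithmetic runs at the full published stream sizes (305,517 / 258,102)
since it is pure set algebra.

## What passing tests do and do not show

The generator produces conditionally independent token draws, uniform
timestamps, no retweet cascades, no user-level topical persistence, and
planted markers that are cleanly class-specific. Passing recovery and
classification tests therefore demonstrates the *pipeline's* correctness —
accounting identities, estimator algebra, rule application — not that the
classifiers would reach any particular AUC on real tweets, whose features
and noise structure are far richer. The published AUCs of the original
hand-coded data are correspondingly out of scope: they depend on
unavailable training data and classifier features.

## Known limitations

- Substring keyword matching has no word boundaries; a token like
  "HPVvaccines" matches "HPV". This mirrors the documented containment
  behaviour but may over-match on unusual text.
- The tree is unpruned beyond depth/min-leaf limits; no cost-complexity
  pruning.
- Language is a single code per record; no language identification is
  performed on text.
- Whether the original analysis used prospective or retrospective metadata
  for merged records is unknown; the retrospective choice here is a
  documented convention.
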