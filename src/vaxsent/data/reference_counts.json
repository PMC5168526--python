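{
  "n_total": 193379,
  "n_merged": 216060,
  "n_users_total": 78643,
  "classes": {
    "positive": {
      "n_tweets": 75393,
      "n_users": 36283,
      "n_link": 57800,
      "n_hashtag": 36638,
      "n_mention": 44558,
      "n_prevention": 20425,
      "n_side_effects": 12921,
      "mean_followers": 8022,
      "median_followers": 459,
      "mean_retweets": 9.7,
      "median_retweets": 1
    },
    "negative": {
      "n_tweets": 48940,
      "n_users": 24010,
      "n_link": 34491,
      "n_hashtag": 21523,
      "n_mention": 31085,
      "n_prevention": 5647,
      "n_side_effects": 22726,
      "mean_followers": 4772,
      "median_followers": 467,
      "mean_retweets": 9.1,
      "median_retweets": 1
    },
    "neutral": {
      "n_tweets": 25110,
      "n_users": 15045,
      "n_link": 18898,
      "n_hashtag": 10890,
      "n_mention": 12659,
      "n_prevention": 6477,
      "n_side_effects": 3787,
      "mean_followers": 6093,
      "median_followers": 445,
      "mean_retweets": 7.8,
      "median_retweets": 0
    },
    "no_mention": {
      "n_tweets": 43936,
      "n_users": 25954,
      "n_link": 26870,
      "n_hashtag": 17915,
      "n_mention": 23747,
      "n_prevention": 3209,
      "n_side_effects": 2619,
      "mean_followers": 6352,
      "median_followers": 381,
      "mean_retweets": 22.0,
      "median_retweets": 0
    }
  },
  "totals": {
    "n_link": 138059,
    "n_hashtag": 86966,
    "n_mention": 112049,
    "n_prevention": 35758,
    "n_side_effects": 42053,
    "mean_followers": 6569,
    "median_followers": 443,
    "mean_retweets": 12.1,
    "median_retweets": 1
  },
  "keyword_counts": {
    "HPV": 191515,
    "HPV vaccine": 75433
  },
  "merge": {
    "n_prospective": 305517,
    "n_retrospective": 258102,
    "n_matched": 216060,
    "n_prospective_only": 89457,
    "n_retrospective_only": 42042
  }
}
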