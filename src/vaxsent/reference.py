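"""Bundled reference cross-tabulation of a year-long English-language
HPV-vaccine tweet corpus (n = 193,379 classified tweets from 216,060 merged).

The fixture stores only raw counts and direct measurements — per-sentiment
tweet / user / link / hashtag / mention / prevention / side-effect counts,
follower and retweet means and medians, per-keyword match counts, and the
dual-source merge sizes.  Every percentage is recomputed from these counts at
run time; the fixture is the arithmetic ground truth for the summary stage.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["load_reference_counts"]


def load_reference_counts() -> dict:
    """Load the bundled reference count fixture as a plain dict."""
    with resources.files("vaxsent.data").joinpath("reference_counts.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)
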