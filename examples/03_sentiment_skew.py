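"""Relative sentiment skew (RSS) and polarization of vaccine headlines.

Each English vaccine headline's raw sentiment (positive minus negative
mass) is adjusted by subtracting its outlet's mean sentiment over
non-vaccine headlines, removing per-outlet tone bias.  The sign of the
adjusted value classifies the headline as negatively or positively
polarized.
"""

from vaxpress import (
    GeneratorConfig,
    LexiconScorer,
    compute_baselines,
    compute_rss,
    polarization_proportions,
    score_corpus,
    tag_corpus,
)
from vaxpress.synthetic import generate

corpus, _ = generate(GeneratorConfig(seed=1))
tags, _ = tag_corpus(corpus)
scores = score_corpus(corpus, LexiconScorer())
baselines = compute_baselines(corpus, tags, scores)
rss = compute_rss(corpus, tags, scores, baselines)

print(f"scored vaccine headlines: {len(rss)}")
print("\nnegative/positive RSS split by period:")
print(polarization_proportions(rss).to_string(index=False))
# The generator plants a slightly negative vaccine-topic sentiment shift
# before the pandemic and a positive one during it, so the negative share
# sits above 50% pre-COVID and near 38% in the pandemic periods —
# pandemic vaccine coverage is majority-positive once outlet tone is
# removed.
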