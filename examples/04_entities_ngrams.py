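"""Manufacturer mentions and their frequent n-grams.

Entity surfaces found in vaccine headlines are canonicalized (hyphenated
partnerships like Pfizer-BioNTech split in two, J&J variants collapsed,
agency abbreviations folded into their expansions) and counted; each
manufacturer's headline subset is then profiled with merged
bigram/trigram tables.
"""

from vaxpress import (
    GeneratorConfig,
    count_entities,
    extract_mentions,
    frequent_ngrams,
    manufacturer_subsets,
    merge_ngrams,
    tag_corpus,
)
from vaxpress.normalize import default_profiles, normalize
from vaxpress.synthetic import generate

corpus, _ = generate(GeneratorConfig(seed=1))
tags, _ = tag_corpus(corpus)
mentions = extract_mentions(t.record for t in tags if t.vaccine)

print("top entities in vaccine headlines:")
print(count_entities(mentions, top_k=8).to_string(index=False))

subsets, matrix = manufacturer_subsets(corpus, tags, mentions)
print("\nmanufacturer mention matrix (headlines per period):")
print(matrix.to_string())

profile = default_profiles()["en"]
recs = subsets[("pfizer", "post_announcement")]
seqs = [normalize(r.text, profile).tokens for r in recs]
table = merge_ngrams(frequent_ngrams(seqs, top_k=10))
table["gram"] = [" ".join(g) for g in table["gram"]]
print("\nfrequent n-grams in post-announcement Pfizer headlines:")
print(table.to_string(index=False))
# The pandemic_total column mirrors how mention counts concentrate in the
# post-announcement period; n-gram tables surface each manufacturer's
# recurring context.
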