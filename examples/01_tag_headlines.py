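"""Tag a small multilingual corpus as vaccine/COVID-related.

Generates a compact synthetic corpus, labels every headline with the
per-language keyword tables (stemmed token matching for fr/it/ru/es,
substring patterns for en/de), and prints the tagging summary.
"""

from vaxpress import GeneratorConfig, tag_corpus
from vaxpress.synthetic import default_sources, generate

config = GeneratorConfig(seed=1, sources=default_sources(per_country=1))
corpus, truth = generate(config)
tags, summary = tag_corpus(corpus)

print(f"records: {summary.total}")
print(f"vaccine-tagged: {summary.vaccine} "
      f"({100 * summary.vaccine_fraction:.2f}%)")
print(f"covid-tagged: {summary.covid}")
for lang, row in sorted(summary.by_language.items()):
    print(f"  {lang}: {row['vaccine']}/{row['total']} vaccine")

exact = sum(t.vaccine == p for t, p in zip(tags, truth["vaccine"]))
print(f"planted labels recovered: {exact}/{len(corpus)}")
# The tagged fraction tracks the planted prevalence (0.1% pre-pandemic,
# 4-7% during the pandemic), and recovery is exact because the generator
# embeds a keyword iff the planted label is true.
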