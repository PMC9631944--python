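"""Weekly vaccine-coverage series and per-period, per-country fractions.

The weekly relative frequency is (vaccine headlines that week) / (all
headlines that week); the period table aggregates the same ratio over
the three study periods split at 9 Jan 2020 (daily coronavirus coverage
begins) and 10 Nov 2020 (day after the Pfizer-BioNTech efficacy press
release).
"""

from vaxpress import (
    GeneratorConfig,
    period_relative_frequency,
    tag_corpus,
    weekly_relative_frequency,
)
from vaxpress.synthetic import generate

corpus, _ = generate(GeneratorConfig(seed=1))
tags, _ = tag_corpus(corpus)

weekly = weekly_relative_frequency(corpus, tags, topic="vaccine")
print("last six weeks of the series:")
print(weekly.tail(6).to_string(index=False))

table = period_relative_frequency(corpus, tags, group_by_country=False)
print("\nvaccine coverage by period (fraction of all headlines):")
print(table.to_string(index=False))
# Coverage steps from ~0.001 before the pandemic to ~0.04 during it and
# ~0.07 after the vaccine announcement — the planted analogue of the
# study corpus's 0.1% → 4% → 6-8% rise.
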