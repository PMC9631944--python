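# Methods

This note documents the models and procedures implemented in `vaxpress`,
the parameters that matter, what the synthetic corpus generator does and
does not emulate, and the design decisions taken where the problem left
room.

## Corpus model

A corpus is an ordered list of headline records with six fields: source
id (one online news source, "ONS"), country (ISO-3166-like, `INT` for
international outlets), language (one of en/fr/de/it/ru/es), UTC
timestamp, title, optional description. Files are JSON lines (UTF-8,
ISO-8601 timestamps) so corpora of millions of records stream line-wise.
Parsing is lenient by default — scraped news data is dirty — with a
counted, logged skip per invalid line; `strict=True` aborts on the first.
All date binning uses UTC calendar dates; period cutoffs are given as
dates without timezones, and half-open `[start, end)` intervals encode
them unambiguously. An optional deduplication pass (same source + title,
keep earliest) exists but is off by default, since re-scraped front pages
are part of the coverage signal.

## Keyword tagging

Each language has a vaccine keyword table and one of two match
strategies:

* **Token matching** (fr, it, ru, es): title and description are
  case-folded, hyphen-split, punctuation-stripped, tokenized and stemmed;
  a keyword fires when its stem equals a token's stem, multi-word
  keywords requiring an adjacent token run. Comparing *stem to stem*
  makes the equivalence class exactly the stemmer's, whichever stemmer
  adapter is plugged in.
* **Substring patterns** (en, de): English text is lemmatized,
  case-folded and punctuation-stripped, then searched as a joined string
  (so `anti-vax` → `anti vax` matches the two-word pattern); German is
  searched as a case-folded raw string, where the single pattern `impf`
  covers the Impf- derivational family.

A headline is vaccine-labeled if any keyword fires in the title *or* the
description. COVID labeling is language-independent: the case-folded text
contains `coronavirus`, `covid-19`, or `covid 19` (the post-hyphen-split
form — both spellings are matched because hyphen handling differs between
raw and normalized paths). Keyword tables and strategies are data, not
code, and can be overridden per language; the Russian defaults are the
stem list {прививк, привива, вакцин, иммунизац, вакцинац}.

This keyword approach deliberately trades recall for precision: a
headline about "jabs" without any keyword stays unlabeled. The test suite
pins this behavior rather than "fixing" it.

## Period partition and frequency series

Three contiguous half-open periods split the corpus: pre-COVID
[2015-07-01, 2020-01-09), before the vaccine announcement [2020-01-09,
2020-11-10), after it [2020-11-10, 2021-04-03). Timestamps outside the
partition get an explicit out-of-range label and are excluded from period
analyses rather than silently binned.

Weekly series use ISO-8601 week numbering. For each week with at least
one in-scope headline, the series reports topic count, total count and
their ratio; empty weeks are absent, not zero — no data is not the same
as zero coverage. The default series pools all sources; per-source series
and a per-country × period table are available. Conservation (weekly
totals sum to the corpus size; topic counts to the tagged count) is a
tested invariant.

## Sentiment and relative sentiment skew

Sentiment is computed for English headlines only (title + description);
non-English records are skipped explicitly, never scored silently. A
scorer adapter returns positive/negative/neutral mass (summing to 1) and
a compound value in [−1, 1]; the raw score is positive minus negative
mass.

Per-outlet tone baselines are the arithmetic mean raw (and compound)
score over the outlet's *non-vaccine* English headlines. The relative
sentiment skew of a vaccine headline is its sentiment minus its outlet's
baseline. Parameters:

* `baseline_scope` — `all_periods` (default) pools an outlet's
  non-vaccine headlines across the whole corpus; `same_period` computes
  one baseline per (outlet, period). Both readings of "the outlet's
  overall tone" are defensible; pooling is the default because it is the
  more stable estimate, and the scope is explicit in every output.
* `min_baseline_n` — baselines from fewer than 30 headlines are flagged
  unreliable; `compute_rss(require_reliable=True)` drops the affected
  headlines. 30 is the usual rule-of-thumb for a stable mean; there is no
  principled value, hence a parameter.

Polarization tables report the negative share |{RSS < 0}| / |{RSS ≠ 0}|
and its complement; exact zeros are counted separately because a sign
split must state its tie policy. Both RSS-based and unadjusted
compound-based polarization are emitted by the pipeline so the adjusted
and unadjusted views can be compared side by side. Cumulative curves are
empirical CDFs evaluated at each distinct RSS value.

The bundled `LexiconScorer` maps words to fixed valences in 0.1 steps
(±0.1 … ±1.0); positive mass is the mean positive valence over tokens,
compound is the valence sum scaled by √n and clipped. It exists so the
sentiment chain is exactly analyzable and hermetically testable; it is
not a model of English sentiment. A VADER-style scorer satisfies the
same protocol.

## Entities and n-grams

Entity detection is an adapter (text → entity surfaces). The bundled
gazetteer matcher scans case-folded text for a configurable lexicon
(seven manufacturers, major health agencies and their abbreviations),
longest match first, word-boundary anchored. Canonicalization: hyphen
splitting applies only when *both* sides of the hyphen are known
manufacturers (Pfizer-BioNTech → pfizer + biontech; Daily-Mail passes
through); "Johnson and Johnson"/"J&J" collapse to "johnson & johnson";
counting is case-folded. FDA, CDC, NIH, WHO and EMA counts are added to
their expansions and removed as rows — total counts are conserved — while
NHS, HHS and PHE stay separate entities. Ties in count tables break
lexicographically so outputs are deterministic.

The manufacturer × period matrix counts each headline once per
manufacturer it mentions (an occurrences mode exists); its
`pandemic_total` column sums the two pandemic periods. N-gram tables
count contiguous bigrams and trigrams within each lemmatized headline
(never across headlines), keep the top 50 by count, then drop any bigram
whose tokens sit contiguously inside a retained trigram with exactly the
same count — the "food drug / drug administr / food drug administr"
collapse. Exact equality is the default merge criterion, with an optional
integer tolerance (default 0); the merge is idempotent.

## Topic-count evaluation

Input preparation lemmatizes, case-folds and POS-filters English vaccine
headlines to content words (nouns incl. proper nouns, verbs, adjectives),
then removes links, outlet-name tokens (config-supplied), the token
"news", and every token containing `vaccin`, `immuniz` or `immunis` —
otherwise the topic model rediscovers the selection keywords as its
dominant topic. `antivax`/`anti vax` are kept: opposition to vaccination
is topic signal, not selection artifact. Documents emptied by cleaning
are dropped and counted.

The harness then runs two steps over a pluggable backend: (1) fit at
each candidate cluster count k and profile the topics (sizes, top words,
outlier fraction); (2) score every topic pair by top-10 word-set overlap
(|intersection| / 10) and flag pairs at ≥ 0.5 for review. The harness
never picks k: near-duplicate topics can share a subject while showing
different keywords, so the final judgement is the operator's. The 0.5
threshold and top-10 depth are conventional defaults, exposed as
parameters. The bundled backend clusters ℓ2-normalized term-count
vectors with seeded KMeans (deterministic, no outlier set); a
transformer + HDBSCAN model plugs into the same `fit(docs, k, seed)`
protocol, where the outlier set is then populated.

## The synthetic corpus generator

The generator emulates the statistical structure of a multi-country
front-page corpus at roughly 1/1000 of study scale, with full planted
ground truth. Defaults:

* **Roster**: 24 sources — two per country for AU, CA, FR, DE, IE, IT,
  NZ, RU, ES, GB, US and an international category; 14 English. A compact
  roster (rather than the study's ~172 outlets) keeps per-source
  non-vaccine headline counts above the baseline reliability minimum at
  desk scale; the roster is a config field.
* **Volume**: per-source weekly headline counts ~ Poisson(4) over
  2015-07-01 … 2021-04-02 → ≈29k records, ~2 s to generate.
* **Prevalence**: vaccine fraction 0.001 / 0.04 / 0.07 in the three
  periods; COVID fraction 0 / 0.25 / 0.25.
* **Sentiment model**: per-source tone baseline b_s ~ Uniform(−0.08,
  0.08); headline raw-score targets ~ Normal(b_s + δ_period·1[vaccine],
  σ) with σ = 0.1, clipped to ±0.35; vaccine-topic shifts δ = −0.018
  pre-COVID and +0.031 during the pandemic. These shifts are the Normal
  quantiles that put 57% resp. 38% of the sign mass below zero — the
  shape of the polarization the pipeline should recover.
* **Entities**: manufacturer names are injected into English vaccine
  headlines per a per-period expected-count plan shaped like the study's
  mention table at 1/100 scale; Pfizer and BioNTech co-assigned to one
  headline render as "Pfizer-BioNTech" so the split rule is exercised.

Construction guarantees: a headline embeds a verbatim keyword surface of
its language iff its vaccine label is true (surfaces are chosen so the
language's matcher provably fires; filler vocabulary is keyword-free), so
tagging must reproduce labels *exactly*, not statistically. English
sentiment is planted through the bundled scorer's own lexicon: sentiment
word slots are filled so the title's valence sum over its token count
approximates the target on the 0.1-valence grid, and the ground truth
stores the exactly achieved score (the scorer's output on the final
text). Quantization deviation is ~0.005 typical; rare long headlines hit
the four-word valence budget, which truncates extreme targets — both
effects are visible in the ground-truth table and bounded in tests.
Generation is deterministic: one seeded RNG, fixed iteration order, so a
fixed config yields byte-identical corpora.

What the generator does **not** emulate: natural language (titles are
keyword/filler/valence-word assemblies), outlet style, topic-correlated
entity placement, weekday/seasonal volume structure, duplicate
headlines, or real VADER behavior on real prose. Passing recovery tests
therefore shows the *pipeline's statistics are computed correctly under
known conditions* — not that the bundled adapters measure real-world
sentiment or topics well. `verify()` re-checks any (corpus, ground
truth) pair: exact label reproduction, per-period prevalence within 4
binomial SEs, per-source achieved-sentiment means within 4σ/√n + 0.01
of the planted baselines (the 0.01 covers valence quantization).

## Problem sizes and numerical choices

The test suite runs on a ~5k-record multilingual corpus (8 countries,
Oct 2019 – Apr 2021) for speed, plus the ~29k default corpus where the
study shape matters; the full suite takes well under a minute. The
acceptance script uses the default roster at 16× weekly volume (~460k
records) and pools four replicate corpora for the polarization split,
because pre-pandemic vaccine headlines are rare by design (~0.1%) and
the sign split over a single replicate's ~200 headlines carries several
points of sampling error; sizes are reported alongside every quantity.

Floating-point expectations: baseline means and RSS are plain float64
arithmetic; shift-invariance and mean-identities are asserted to 1e-12,
not exactly, to allow summation rounding. Sorting tie-breaks
(lexicographic on grams/entities; week order by ISO year, week) make all
tables deterministic. Degenerate inputs fail loudly: empty groups,
missing baselines, unsupported languages and missing adapters raise
typed errors rather than returning defaults.

## Known limitations

* The bundled stemmer/lemmatizer/POS tagger are intentionally minimal
  rule systems tuned to the vaccine-keyword equivalence classes; general
  linguistic coverage requires the production adapters (Snowball,
  TreeTagger, spaCy).
* Sentiment, topics and n-grams are English-only, mirroring the scope of
  the analysis the package implements; tagging and entity counting are
  multilingual.
* The keyword approach undercounts vaccine coverage (precision over
  recall) — a property, not a bug, but one to keep in mind when reading
  coverage fractions as absolute levels.
* `same_period` baselines with sparse outlets can fall below the
  reliability minimum; the pipeline surfaces this rather than imputing.
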