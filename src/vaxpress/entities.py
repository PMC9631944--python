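"""Organization/company entity extraction, canonicalization and counting,
plus manufacturer-specific frequent n-grams.

Entity detection goes through a pluggable NER adapter (text → entity
surface strings).  The bundled backend is a dictionary matcher over a
configurable organization/manufacturer lexicon, so the whole chain runs
without statistical models; a spaCy pipeline plugs in through the same
protocol.

Canonicalization applies the study's consolidation rules: hyphen-joined
manufacturer pairs ("Pfizer-BioNTech") split into two mentions, Johnson &
Johnson spelling variants collapse, counting is case-folded, and the five
agency abbreviations (FDA, CDC, NIH, WHO, EMA) are added to their
expansions.  NHS, HHS and PHE are deliberately left as-is.

N-gram tables count contiguous bigrams and trigrams over lemmatized
headline tokens; near-duplicate bigrams are merged away when a trigram
containing them occurs with the same count (the "food drug" +
"drug administr" → "food drug administr" rule).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Iterable, Protocol, Sequence

import pandas as pd

from .corpus import Corpus, HeadlineRecord
from .keywords import TagResult
from .normalize import casefold_text
from .timeline import OUT_OF_RANGE, PeriodPartition, assign_period

#: The seven COVID-19 vaccine manufacturers tracked throughout.
MANUFACTURERS: tuple[str, ...] = (
    "astrazeneca",
    "biontech",
    "johnson & johnson",
    "moderna",
    "oxford",
    "pfizer",
    "sputnik v",
)

#: Spelling variants collapsed before counting.
DEFAULT_ALIASES: dict[str, str] = {
    "johnson and johnson": "johnson & johnson",
    "j&j": "johnson & johnson",
}

#: Abbreviations whose counts are added to their expansions.  NHS/HHS/PHE
#: are intentionally absent: they are assessed as entities in their own
#: right.
DEFAULT_ABBREVIATIONS: dict[str, str] = {
    "fda": "food and drug administration",
    "cdc": "center for disease control",
    "nih": "national institute of health",
    "who": "world health organization",
    "ema": "european medicines authority",
}

#: Organizations the bundled dictionary NER recognizes besides the
#: manufacturers and abbreviations.
DEFAULT_ORGANIZATIONS: tuple[str, ...] = (
    "food and drug administration",
    "center for disease control",
    "national institute of health",
    "world health organization",
    "european medicines authority",
    "nhs",
    "hhs",
    "phe",
    "european union",
    "united nations",
    "rospotrebnadzor",
    "rdif",
)


@dataclass(frozen=True)
class EntityMention:
    """One canonical entity occurrence inside one headline."""

    record: HeadlineRecord
    surface: str
    canonical: str


class NerBackend(Protocol):
    def entities(self, text: str) -> list[str]:
        """Return organization/company entity surfaces found in ``text``."""
        ...


class DictionaryNer:
    """Deterministic gazetteer matcher.

    Scans case-folded text for known entity surfaces (longest first,
    non-overlapping, word-boundary anchored).  Hyphen-joined manufacturer
    pairs are recognized as single surfaces so the downstream split rule
    has something to split.
    """

    def __init__(self, lexicon: Iterable[str] | None = None):
        if lexicon is None:
            lexicon = list(MANUFACTURERS) + list(DEFAULT_ORGANIZATIONS) + list(
                DEFAULT_ABBREVIATIONS
            ) + list(DEFAULT_ALIASES)
            # hyphenated partnership forms
            lexicon += ["pfizer-biontech", "astrazeneca-oxford", "oxford-astrazeneca"]
        surfaces = sorted({casefold_text(s) for s in lexicon}, key=len, reverse=True)
        self._pattern = re.compile(
            "|".join(r"(?<!\w)" + re.escape(s) + r"(?!\w)" for s in surfaces)
        )

    def entities(self, text: str) -> list[str]:
        return self._pattern.findall(casefold_text(text))


def normalize_entity(
    surface: str,
    manufacturer_lexicon: Sequence[str] = MANUFACTURERS,
    aliases: dict[str, str] | None = None,
) -> list[str]:
    """Canonicalize one entity surface into one or two canonical entities.

    Case-folds, applies the alias map, and splits a hyphen-joined pair
    into two entities when *both* sides are known manufacturers (so
    ordinary hyphenated names pass through untouched).
    """
    if not surface:
        raise ValueError("empty entity surface")
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    s = casefold_text(surface.strip())
    s = aliases.get(s, s)
    lex = {casefold_text(m) for m in manufacturer_lexicon}
    if "-" in s:
        left, _, right = s.partition("-")
        left, right = aliases.get(left, left), aliases.get(right, right)
        if left in lex and right in lex:
            return [left, right]
    return [s]


def extract_mentions(
    records: Iterable[HeadlineRecord],
    backend: NerBackend | None = None,
    manufacturer_lexicon: Sequence[str] = MANUFACTURERS,
    aliases: dict[str, str] | None = None,
) -> list[EntityMention]:
    """Run NER over headlines and canonicalize every hit."""
    backend = backend or DictionaryNer()
    mentions: list[EntityMention] = []
    for rec in records:
        for surface in backend.entities(rec.text):
            for canonical in normalize_entity(surface, manufacturer_lexicon, aliases):
                mentions.append(EntityMention(rec, surface, canonical))
    return mentions


def count_entities(
    mentions: Iterable[EntityMention | str],
    abbreviation_map: dict[str, str] | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Tally canonical entities, consolidating abbreviations.

    Abbreviation counts are *added* to their expansion's count and the
    abbreviation row removed, so the total count is conserved.  Rows are
    sorted by descending count, ties broken lexicographically.  Columns:
    ``entity``, ``count``.
    """
    abbreviation_map = (
        DEFAULT_ABBREVIATIONS if abbreviation_map is None else abbreviation_map
    )
    tally: Counter[str] = Counter()
    for m in mentions:
        tally[m.canonical if isinstance(m, EntityMention) else m] += 1
    for abbr, expansion in abbreviation_map.items():
        if abbr in tally:
            tally[expansion] += tally.pop(abbr)
    rows = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        rows = rows[:top_k]
    return pd.DataFrame(rows, columns=["entity", "count"])


def manufacturer_subsets(
    corpus: Corpus,
    tags: Sequence[TagResult],
    mentions: Sequence[EntityMention],
    manufacturers: Sequence[str] = MANUFACTURERS,
    partition: PeriodPartition | None = None,
    count_occurrences: bool = False,
) -> tuple[dict[tuple[str, str], list[HeadlineRecord]], pd.DataFrame]:
    """Per-(manufacturer, period) headline subsets and the count matrix.

    A headline joins a manufacturer's subset when its canonical mentions
    include that manufacturer.  The matrix has one row per manufacturer
    and one column per period plus a ``pandemic_total`` column summing the
    two pandemic periods.  By default each headline counts once per
    manufacturer; ``count_occurrences`` counts every mention.
    """
    if len(tags) != len(corpus):
        raise ValueError("tags must cover the corpus exactly")
    partition = partition or PeriodPartition()
    if not manufacturers:
        raise ValueError("manufacturer list must be non-empty")
    known = {casefold_text(m) for m in manufacturers}

    by_record: dict[int, list[EntityMention]] = {}
    for men in mentions:
        if men.canonical in known:
            by_record.setdefault(id(men.record), []).append(men)

    subsets: dict[tuple[str, str], list[HeadlineRecord]] = {}
    counts: Counter[tuple[str, str]] = Counter()
    for rec in corpus:
        men_list = by_record.get(id(rec))
        if not men_list:
            continue
        period = assign_period(rec.timestamp, partition)
        if period == OUT_OF_RANGE:
            continue
        per_manu: Counter[str] = Counter(m.canonical for m in men_list)
        for manu, occ in per_manu.items():
            subsets.setdefault((manu, period), []).append(rec)
            counts[(manu, period)] += occ if count_occurrences else 1

    periods = list(partition.labels)
    matrix = pd.DataFrame(
        [
            {
                "manufacturer": manu,
                **{p: counts.get((casefold_text(manu), p), 0) for p in periods},
            }
            for manu in (casefold_text(m) for m in manufacturers)
        ]
    ).set_index("manufacturer")
    matrix["pandemic_total"] = matrix[periods[1]] + matrix[periods[2]]
    return subsets, matrix


# --------------------------------------------------------------------------
# N-grams


def frequent_ngrams(
    token_sequences: Iterable[Sequence[str]],
    top_k: int = 50,
    orders: tuple[int, ...] = (2, 3),
) -> pd.DataFrame:
    """Most frequent contiguous bigrams and trigrams over headlines.

    N-grams never cross headline boundaries.  The combined bigram+trigram
    table is cut to the ``top_k`` most frequent entries with a
    deterministic tie-break (lexicographic on the gram).  Columns:
    ``gram`` (token tuple), ``n``, ``count``.
    """
    tally: Counter[tuple[str, ...]] = Counter()
    empty = True
    for seq in token_sequences:
        empty = False
        toks = list(seq)
        for n in orders:
            for i in range(len(toks) - n + 1):
                tally[tuple(toks[i : i + n])] += 1
    if empty:
        raise ValueError("no token sequences given")
    rows = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return pd.DataFrame(
        [(gram, len(gram), count) for gram, count in rows],
        columns=["gram", "n", "count"],
    )


def merge_ngrams(table: pd.DataFrame, tolerance: int = 0) -> pd.DataFrame:
    """Drop bigrams that merely echo a trigram in the table.

    A bigram is removed when its tokens occur contiguously inside some
    retained trigram and the two counts differ by at most ``tolerance``
    (default 0: exact equality, e.g. ("food","drug") and
    ("drug","administr") both at the count of ("food","drug","administr")).
    Trigrams are always retained; the operation is idempotent.
    """
    trigrams = [
        (tuple(row.gram), int(row.count))
        for row in table.itertuples(index=False)
        if row.n == 3
    ]

    def echoed(gram: tuple[str, ...], count: int) -> bool:
        for tri, tri_count in trigrams:
            if abs(count - tri_count) <= tolerance and (
                tri[:2] == gram or tri[1:] == gram
            ):
                return True
        return False

    keep = [
        not (row.n == 2 and echoed(tuple(row.gram), int(row.count)))
        for row in table.itertuples(index=False)
    ]
    return table[keep].reset_index(drop=True)
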