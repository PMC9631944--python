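"""Keyword-based labeling of vaccine- and COVID-related headlines.

Each language has a keyword set and a match strategy.  French, Italian,
Russian and Spanish use token matching: the title and description are
tokenized and stemmed, and a keyword fires when its stem equals a token's
stem (multi-word keywords must match an adjacent token run).  English and
German use substring patterns: the title and description are kept as
strings (lemmatized and case-folded for English, case-folded raw for
German) and a keyword fires when it occurs as a substring — e.g. the
German prefix ``impf`` catches Impfung, impfen and Impfgegner alike.

A headline is vaccine-labeled if any vaccine keyword fires in the title or
the description; COVID labeling uses ``coronavirus`` / ``covid-19`` in any
language.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import Corpus, HeadlineRecord
from .normalize import (
    NormalizationProfile,
    casefold_text,
    default_profiles,
    normalize,
)

TOKEN_MATCH = "token_match"
SUBSTRING_PATTERN = "substring_pattern"

#: Which match strategy each language uses.
STRATEGY_BY_LANGUAGE = {
    "en": SUBSTRING_PATTERN,
    "de": SUBSTRING_PATTERN,
    "fr": TOKEN_MATCH,
    "it": TOKEN_MATCH,
    "ru": TOKEN_MATCH,
    "es": TOKEN_MATCH,
}

#: Default per-language vaccine keywords.  Non-English entries are stems;
#: English entries are matched as substrings of the lemmatized headline.
DEFAULT_VACCINE_KEYWORDS: dict[str, tuple[str, ...]] = {
    "en": ("vaccin", "immunis", "immuniz", "anti vax", "antivax"),
    "fr": ("vaccin", "antivaccin", "immunis"),
    "de": ("impf",),
    "it": ("vaccin", "antivaccin", "immunizz"),
    "ru": ("прививк", "привива", "вакцин", "иммунизац", "вакцинац"),
    "es": ("vacun", "antivacun", "inmuniz"),
}

#: COVID keywords, applied language-independently as case-folded
#: substrings.  "covid 19" covers the post-hyphen-split form.
DEFAULT_COVID_KEYWORDS: tuple[str, ...] = ("coronavirus", "covid-19", "covid 19")


@dataclass(frozen=True)
class KeywordSet:
    """Keywords plus match strategy for one language."""

    language: str
    keywords: tuple[str, ...]
    strategy: str

    def __post_init__(self):
        if self.strategy not in (TOKEN_MATCH, SUBSTRING_PATTERN):
            raise ValueError(f"unknown strategy: {self.strategy!r}")
        if not self.keywords:
            raise ValueError("keyword set must be non-empty")
        object.__setattr__(
            self, "keywords", tuple(casefold_text(k) for k in self.keywords)
        )


@dataclass(frozen=True)
class TagResult:
    """Vaccine/COVID labels for one headline, with the keywords that fired."""

    record: HeadlineRecord
    vaccine: bool
    covid: bool
    matched_terms: tuple[str, ...] = ()


def default_keyword_sets() -> dict[str, KeywordSet]:
    """The default vaccine keyword table, one :class:`KeywordSet` per
    language."""
    return {
        lang: KeywordSet(lang, kws, STRATEGY_BY_LANGUAGE[lang])
        for lang, kws in DEFAULT_VACCINE_KEYWORDS.items()
    }


def covid_keyword_set() -> tuple[str, ...]:
    return DEFAULT_COVID_KEYWORDS


def _token_runs_match(tokens: list[str], key_tokens: list[str]) -> bool:
    k = len(key_tokens)
    if k == 0 or k > len(tokens):
        return False
    return any(tokens[i : i + k] == key_tokens for i in range(len(tokens) - k + 1))


def _match_keywords_in_text(
    text: str, kset: KeywordSet, profile: NormalizationProfile
) -> list[str]:
    """Return the keywords from ``kset`` that fire in one text field."""
    hits: list[str] = []
    if kset.strategy == TOKEN_MATCH:
        stemmer = profile.stemmer
        if stemmer is None:
            raise ValueError(
                f"token matching for {kset.language!r} requires a stemmer"
            )
        tokens = list(normalize(text, profile))
        for kw in kset.keywords:
            key_tokens = [stemmer.stem(part) for part in kw.split()]
            if _token_runs_match(tokens, key_tokens):
                hits.append(kw)
    else:
        if profile.mode == "raw":
            haystack = casefold_text(text)
        else:
            haystack = normalize(text, profile).joined()
        for kw in kset.keywords:
            if kw in haystack:
                hits.append(kw)
    return hits


def tag_headline(
    record: HeadlineRecord,
    sets: dict[str, KeywordSet],
    profiles: dict[str, NormalizationProfile] | None = None,
    covid_keywords: tuple[str, ...] = DEFAULT_COVID_KEYWORDS,
) -> TagResult:
    """Label one headline as vaccine- and/or COVID-related.

    A keyword present in either the title or the description fires; the
    two fields are matched independently (a description-only hit still
    tags the record).
    """
    profiles = profiles if profiles is not None else default_profiles()
    if record.language not in sets:
        raise ValueError(f"no keyword set for language {record.language!r}")
    if record.language not in profiles:
        raise ValueError(f"no normalization profile for {record.language!r}")
    kset = sets[record.language]
    profile = profiles[record.language]

    matched: list[str] = []
    for fld in (record.title, record.description):
        if fld:
            for kw in _match_keywords_in_text(fld, kset, profile):
                if kw not in matched:
                    matched.append(kw)

    covid_haystack = casefold_text(record.text)
    covid = any(kw in covid_haystack for kw in covid_keywords)
    return TagResult(
        record=record,
        vaccine=bool(matched),
        covid=covid,
        matched_terms=tuple(matched),
    )


@dataclass
class TagSummary:
    """Per-corpus tagging totals."""

    total: int
    vaccine: int
    covid: int
    by_language: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def vaccine_fraction(self) -> float:
        return self.vaccine / self.total if self.total else 0.0


def tag_corpus(
    corpus: Corpus,
    sets: dict[str, KeywordSet] | None = None,
    profiles: dict[str, NormalizationProfile] | None = None,
    covid_keywords: tuple[str, ...] = DEFAULT_COVID_KEYWORDS,
) -> tuple[list[TagResult], TagSummary]:
    """Tag every record of a corpus; returns per-record results plus a
    summary with vaccine/COVID counts and a per-language breakdown."""
    sets = sets if sets is not None else default_keyword_sets()
    profiles = profiles if profiles is not None else default_profiles()
    results = [
        tag_headline(rec, sets, profiles, covid_keywords) for rec in corpus
    ]
    by_language: dict[str, dict[str, int]] = {}
    n_vax = n_cov = 0
    for res in results:
        lang = res.record.language
        row = by_language.setdefault(lang, {"total": 0, "vaccine": 0, "covid": 0})
        row["total"] += 1
        if res.vaccine:
            row["vaccine"] += 1
            n_vax += 1
        if res.covid:
            row["covid"] += 1
            n_cov += 1
    summary = TagSummary(
        total=len(results), vaccine=n_vax, covid=n_cov, by_language=by_language
    )
    return results, summary
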