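"""Headline sentiment scoring and relative sentiment skew (RSS).

Sentiment is restricted to English headlines and produced by a pluggable
scorer adapter returning positive/negative/neutral mass and a compound
value.  A headline's *raw score* is positive mass minus negative mass.

News outlets differ in overall tone, so raw topic sentiment confounds
outlet tone with topic sentiment.  The *relative sentiment skew* removes
the outlet effect: for a topic headline ``h`` from source ``s``,

    RSS(h) = sent(h) − mean sentiment of s's non-topic headlines

where the baseline mean is taken over all periods by default (a
``same_period`` scope is available).  RSS is invariant to per-source
additive shifts by construction.

The bundled :class:`LexiconScorer` is a deterministic signed-lexicon
scorer: each word carries a fixed valence in [−1, 1]; positive/negative
mass is the mean positive/negative valence over tokens.  A VADER-style
scorer plugs in through the same adapter protocol.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Hashable, Protocol, Sequence

import pandas as pd

from .corpus import Corpus, HeadlineRecord
from .keywords import TagResult
from .timeline import OUT_OF_RANGE, PeriodPartition, assign_period


class NotEnglishError(ValueError):
    """Sentiment scoring was requested for a non-English headline."""


class MissingBaselineError(KeyError):
    """A topic headline's source has no usable sentiment baseline."""


@dataclass(frozen=True)
class SentimentScore:
    """Positive/negative/neutral mass plus compound value for one headline.

    ``positive + negative + neutral`` must be 1 (tolerance 1e-6);
    ``raw`` is derived as ``positive − negative``.
    """

    positive: float
    negative: float
    neutral: float
    compound: float

    def __post_init__(self):
        if abs(self.positive + self.negative + self.neutral - 1.0) > 1e-6:
            raise ValueError("positive + negative + neutral must sum to 1")
        if not -1.0 <= self.compound <= 1.0:
            raise ValueError("compound must lie in [-1, 1]")

    @property
    def raw(self) -> float:
        return self.positive - self.negative


class SentimentScorer(Protocol):
    def score(self, text: str) -> SentimentScore: ...


# --------------------------------------------------------------------------
# Bundled deterministic lexicon scorer

#: Signed valence lexicon, graded in 0.1 steps.  Word choice avoids every
#: vaccine/COVID keyword substring so sentiment words never affect tagging.
DEFAULT_VALENCE_LEXICON: dict[str, float] = {
    "superb": 1.0, "excellent": 0.9, "wonderful": 0.8, "great": 0.7,
    "hopeful": 0.6, "good": 0.5, "promising": 0.4, "encouraging": 0.3,
    "helpful": 0.2, "fine": 0.1,
    "catastrophic": -1.0, "horrific": -0.9, "terrible": -0.8, "awful": -0.7,
    "alarming": -0.6, "bad": -0.5, "worrying": -0.4, "troubling": -0.3,
    "disappointing": -0.2, "poor": -0.1,
}

_WORD_RE = re.compile(r"[\w'’]+", re.UNICODE)


@dataclass(frozen=True)
class LexiconScorer:
    """Deterministic signed-lexicon sentiment scorer.

    Tokens are case-folded words; positive mass is the summed positive
    valence divided by the token count (likewise negative), the remainder
    is neutral, and the compound value is the valence sum scaled by
    ``sqrt(n)`` and clipped to [−1, 1].
    """

    lexicon: tuple[tuple[str, float], ...] = tuple(
        sorted(DEFAULT_VALENCE_LEXICON.items())
    )

    def _valences(self) -> dict[str, float]:
        return dict(self.lexicon)

    def score(self, text: str) -> SentimentScore:
        tokens = [t.casefold() for t in _WORD_RE.findall(text)]
        if not tokens:
            return SentimentScore(0.0, 0.0, 1.0, 0.0)
        lex = self._valences()
        n = len(tokens)
        pos = sum(lex.get(t, 0.0) for t in tokens if lex.get(t, 0.0) > 0) / n
        neg = -sum(lex.get(t, 0.0) for t in tokens if lex.get(t, 0.0) < 0) / n
        total = sum(lex.get(t, 0.0) for t in tokens)
        compound = max(-1.0, min(1.0, total / math.sqrt(n)))
        return SentimentScore(pos, neg, 1.0 - pos - neg, compound)


# --------------------------------------------------------------------------
# Scoring and baselines


def score_headline(record: HeadlineRecord, scorer: SentimentScorer) -> SentimentScore:
    """Score one English headline (title + description).

    Raises :class:`NotEnglishError` for other languages — sentiment
    analysis is defined on English text only.
    """
    if record.language != "en":
        raise NotEnglishError(
            f"sentiment is English-only; got language {record.language!r}"
        )
    return scorer.score(record.text)


def score_corpus(
    corpus: Corpus, scorer: SentimentScorer
) -> list[SentimentScore | None]:
    """Score every English record; non-English slots are ``None``.

    The result is positionally aligned with the corpus.
    """
    return [
        scorer.score(rec.text) if rec.language == "en" else None for rec in corpus
    ]


@dataclass(frozen=True)
class OnsBaseline:
    """Mean non-topic sentiment for one news source (its tone baseline)."""

    source_id: str
    mean_raw: float
    mean_compound: float
    n: int
    baseline_scope: str = "all_periods"  # or "same_period"
    period: str | None = None
    reliable: bool = True


def compute_baselines(
    corpus: Corpus,
    tags: Sequence[TagResult],
    scores: Sequence[SentimentScore | None],
    scope: str = "all_periods",
    partition: PeriodPartition | None = None,
    min_n: int = 30,
) -> dict[Hashable, OnsBaseline]:
    """Per-source mean sentiment over non-topic (non-vaccine) English
    headlines.

    With ``scope="all_periods"`` the map is keyed by ``source_id``; with
    ``scope="same_period"`` by ``(source_id, period)``.  Baselines built
    from fewer than ``min_n`` headlines are flagged unreliable.  A source
    with English topic headlines but zero scored non-topic headlines has
    no baseline and will surface as :class:`MissingBaselineError` later.
    """
    if scope not in ("all_periods", "same_period"):
        raise ValueError(f"unknown baseline scope {scope!r}")
    if not (len(corpus) == len(tags) == len(scores)):
        raise ValueError("corpus, tags and scores must be aligned")
    partition = partition or PeriodPartition()

    sums: dict[Hashable, list[float]] = {}
    for rec, tag, sc in zip(corpus, tags, scores):
        if sc is None or tag.vaccine:
            continue
        if scope == "same_period":
            period = assign_period(rec.timestamp, partition)
            if period == OUT_OF_RANGE:
                continue
            key: Hashable = (rec.source_id, period)
        else:
            key = rec.source_id
        acc = sums.setdefault(key, [0.0, 0.0, 0])
        acc[0] += sc.raw
        acc[1] += sc.compound
        acc[2] += 1

    out: dict[Hashable, OnsBaseline] = {}
    for key, (s_raw, s_comp, n) in sums.items():
        source_id, period = (key if scope == "same_period" else (key, None))
        out[key] = OnsBaseline(
            source_id=source_id,
            mean_raw=s_raw / n,
            mean_compound=s_comp / n,
            n=n,
            baseline_scope=scope,
            period=period,
            reliable=n >= min_n,
        )
    return out


@dataclass(frozen=True)
class RssValue:
    """Baseline-adjusted sentiment of one topic headline."""

    record: HeadlineRecord
    rss_raw: float
    rss_compound: float
    period: str


def compute_rss(
    corpus: Corpus,
    tags: Sequence[TagResult],
    scores: Sequence[SentimentScore | None],
    baselines: dict[Hashable, OnsBaseline],
    partition: PeriodPartition | None = None,
    require_reliable: bool = False,
) -> list[RssValue]:
    """Relative sentiment skew for every scored vaccine-tagged headline.

    ``rss = sent(h) − baseline mean of h's source`` for both the raw and
    the compound measure.  Raises :class:`MissingBaselineError` if a topic
    headline's source (or source–period cell, under ``same_period``
    baselines) has no baseline.  With ``require_reliable`` headlines whose
    baseline failed the minimum-n guard are dropped instead of adjusted.
    """
    if not (len(corpus) == len(tags) == len(scores)):
        raise ValueError("corpus, tags and scores must be aligned")
    partition = partition or PeriodPartition()
    same_period = any(b.baseline_scope == "same_period" for b in baselines.values())

    out: list[RssValue] = []
    for rec, tag, sc in zip(corpus, tags, scores):
        if sc is None or not tag.vaccine:
            continue
        period = assign_period(rec.timestamp, partition)
        key: Hashable = (rec.source_id, period) if same_period else rec.source_id
        if key not in baselines:
            raise MissingBaselineError(
                f"no sentiment baseline for {key!r}"
            )
        base = baselines[key]
        if require_reliable and not base.reliable:
            continue
        out.append(
            RssValue(
                record=rec,
                rss_raw=sc.raw - base.mean_raw,
                rss_compound=sc.compound - base.mean_compound,
                period=period,
            )
        )
    return out


# --------------------------------------------------------------------------
# Polarization summaries


def polarization_proportions(
    rss_values: Sequence[RssValue],
    group_by: Callable[[RssValue], Hashable] = lambda rv: rv.period,
    measure: str = "raw",
) -> pd.DataFrame:
    """Negative/positive proportions of RSS values per group.

    The sign split excludes exact zeros (reported in ``n_zero``):
    ``negative_fraction = |rss < 0| / |rss ≠ 0|`` and the positive
    fraction is its complement.
    """
    if not rss_values:
        raise ValueError("no RSS values to summarize")
    attr = "rss_raw" if measure == "raw" else "rss_compound"
    rows: dict[Hashable, list[int]] = {}
    for rv in rss_values:
        v = getattr(rv, attr)
        acc = rows.setdefault(group_by(rv), [0, 0, 0])  # neg, pos, zero
        if v < 0:
            acc[0] += 1
        elif v > 0:
            acc[1] += 1
        else:
            acc[2] += 1
    records = []
    for group, (neg, pos, zero) in sorted(rows.items(), key=lambda kv: str(kv[0])):
        nonzero = neg + pos
        if nonzero == 0:
            raise ValueError(f"group {group!r} has only zero RSS values")
        records.append(
            {
                "group": group,
                "n": neg + pos + zero,
                "n_zero": zero,
                "negative_fraction": neg / nonzero,
                "positive_fraction": pos / nonzero,
            }
        )
    return pd.DataFrame.from_records(records)


def cumulative_rss_curve(
    rss_values: Sequence[RssValue],
    group_by: Callable[[RssValue], Hashable] = lambda rv: rv.period,
    measure: str = "raw",
) -> pd.DataFrame:
    """Empirical cumulative distribution of RSS per group.

    One row per distinct RSS value: the fraction of the group's headlines
    with RSS ≤ that value.  Curves are nondecreasing and end at 1.
    """
    if not rss_values:
        raise ValueError("no RSS values to summarize")
    attr = "rss_raw" if measure == "raw" else "rss_compound"
    groups: dict[Hashable, list[float]] = {}
    for rv in rss_values:
        groups.setdefault(group_by(rv), []).append(getattr(rv, attr))
    records = []
    for group in sorted(groups, key=str):
        values = sorted(groups[group])
        n = len(values)
        seen = 0
        i = 0
        while i < n:
            j = i
            while j < n and values[j] == values[i]:
                j += 1
            seen = j
            records.append(
                {
                    "group": group,
                    "rss": values[i],
                    "cumulative_fraction": seen / n,
                }
            )
            i = j
    return pd.DataFrame.from_records(records)
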