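"""Study-period partitioning and weekly relative-frequency series.

The corpus is split into three half-open date intervals: the pre-COVID era,
the pandemic before the vaccine announcement, and the pandemic after it
(the announcement being the 9 Nov 2020 efficacy press release).  For each
ISO week the relative frequency of a topic is the number of topic-tagged
headlines divided by all headlines that week; weeks with no headlines are
absent from the series rather than zero-filled, since no data is not the
same as zero coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from typing import Literal, Sequence

import pandas as pd

from .corpus import Corpus
from .keywords import TagResult

OUT_OF_RANGE = "out_of_range"

PRE_COVID = "pre_covid"
PRE_ANNOUNCEMENT = "pre_announcement"
POST_ANNOUNCEMENT = "post_announcement"


@dataclass(frozen=True)
class PeriodPartition:
    """Three labeled, contiguous, half-open date intervals.

    Defaults follow the study timeline: pre-COVID from 1 Jul 2015 until
    daily coronavirus coverage began on 9 Jan 2020; pre-announcement until
    the Pfizer–BioNTech efficacy press release (9 Nov 2020, so the third
    period starts 10 Nov 2020); post-announcement through 2 Apr 2021.
    Boundaries are half-open ``[start, end)`` on UTC calendar dates.
    """

    start: date = date(2015, 7, 1)
    covid_outbreak: date = date(2020, 1, 9)
    vaccine_announcement: date = date(2020, 11, 10)
    end: date = date(2021, 4, 3)

    def __post_init__(self):
        if not (self.start < self.covid_outbreak < self.vaccine_announcement < self.end):
            raise ValueError("period boundaries must be strictly increasing")

    @property
    def labels(self) -> tuple[str, str, str]:
        return (PRE_COVID, PRE_ANNOUNCEMENT, POST_ANNOUNCEMENT)

    def intervals(self) -> dict[str, tuple[date, date]]:
        return {
            PRE_COVID: (self.start, self.covid_outbreak),
            PRE_ANNOUNCEMENT: (self.covid_outbreak, self.vaccine_announcement),
            POST_ANNOUNCEMENT: (self.vaccine_announcement, self.end),
        }


def assign_period(timestamp: datetime | date, partition: PeriodPartition) -> str:
    """Label a timestamp with its study period.

    Returns one of the three period labels, or ``"out_of_range"`` for
    timestamps outside the partition's coverage (those are excluded from
    period analyses, never silently binned).
    """
    d = timestamp.date() if isinstance(timestamp, datetime) else timestamp
    for label, (lo, hi) in partition.intervals().items():
        if lo <= d < hi:
            return label
    return OUT_OF_RANGE


def _tags_frame(tags: Sequence[TagResult], topic: str) -> pd.DataFrame:
    if topic not in ("vaccine", "covid"):
        raise ValueError(f"unknown topic {topic!r}")
    return pd.DataFrame(
        {
            "source_id": [t.record.source_id for t in tags],
            "country": [t.record.country for t in tags],
            "date": [t.record.timestamp.date() for t in tags],
            "tagged": [getattr(t, topic) for t in tags],
        }
    )


def weekly_relative_frequency(
    corpus: Corpus,
    tags: Sequence[TagResult],
    topic: Literal["vaccine", "covid"] = "vaccine",
    scope: str | None = None,
) -> pd.DataFrame:
    """Weekly topic relative-frequency series.

    For every ISO week with at least one headline in scope, reports the
    number of topic-tagged headlines, the total, and their ratio.  ``scope``
    restricts to one source id; ``None`` pools all sources (the default
    headline series).

    Returns a DataFrame with columns ``iso_year``, ``iso_week``,
    ``topic_count``, ``total_count``, ``relative_frequency``, sorted by
    week.
    """
    if len(tags) != len(corpus):
        raise ValueError("tags must cover the corpus exactly")
    df = _tags_frame(tags, topic)
    if scope is not None:
        df = df[df["source_id"] == scope]
        if df.empty:
            raise ValueError(f"no records for source {scope!r}")
    iso = pd.DatetimeIndex(pd.to_datetime(df["date"])).isocalendar()
    df = df.assign(iso_year=iso["year"].values, iso_week=iso["week"].values)
    grouped = (
        df.groupby(["iso_year", "iso_week"], as_index=False)
        .agg(topic_count=("tagged", "sum"), total_count=("tagged", "size"))
        .astype({"topic_count": int, "total_count": int})
    )
    grouped["relative_frequency"] = grouped["topic_count"] / grouped["total_count"]
    return grouped.sort_values(["iso_year", "iso_week"], ignore_index=True)


def period_relative_frequency(
    corpus: Corpus,
    tags: Sequence[TagResult],
    topic: Literal["vaccine", "covid"] = "vaccine",
    partition: PeriodPartition | None = None,
    group_by_country: bool = True,
) -> pd.DataFrame:
    """Topic relative frequency per period, optionally per country.

    Rows appear only for (country, period) cells with at least one
    headline; out-of-range records are dropped.  Columns: ``country`` (if
    grouped), ``period``, ``topic_count``, ``total_count``,
    ``relative_frequency``.
    """
    if len(tags) != len(corpus):
        raise ValueError("tags must cover the corpus exactly")
    partition = partition or PeriodPartition()
    df = _tags_frame(tags, topic)
    df["period"] = [assign_period(t.record.timestamp, partition) for t in tags]
    df = df[df["period"] != OUT_OF_RANGE]
    keys = ["country", "period"] if group_by_country else ["period"]
    grouped = (
        df.groupby(keys, as_index=False)
        .agg(topic_count=("tagged", "sum"), total_count=("tagged", "size"))
        .astype({"topic_count": int, "total_count": int})
    )
    grouped["relative_frequency"] = grouped["topic_count"] / grouped["total_count"]
    order = pd.CategoricalDtype(partition.labels, ordered=True)
    grouped["period"] = grouped["period"].astype(order)
    return grouped.sort_values(keys, ignore_index=True)
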