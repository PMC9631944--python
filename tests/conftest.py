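"""Shared fixtures: small and default-scale synthetic corpora."""

from __future__ import annotations

from datetime import date

import pytest

from vaxpress.synthetic import GeneratorConfig, SourceSpec, generate
from vaxpress.timeline import PeriodPartition


def small_partition() -> PeriodPartition:
    return PeriodPartition(
        start=date(2019, 10, 1),
        covid_outbreak=date(2020, 1, 9),
        vaccine_announcement=date(2020, 11, 10),
        end=date(2021, 4, 3),
    )


def small_config(seed: int = 11, weekly_volume: float = 6.0) -> GeneratorConfig:
    """A fast multilingual config: ~5k records over Oct 2019 – Apr 2021."""
    sources = tuple(
        SourceSpec(f"{c.lower()}_s{i}", c, lang, weekly_volume)
        for c, lang in (
            ("US", "en"), ("GB", "en"), ("DE", "de"), ("FR", "fr"),
            ("IT", "it"), ("RU", "ru"), ("ES", "es"), ("INT", "en"),
        )
        for i in (1, 2)
    )
    return GeneratorConfig(
        seed=seed,
        sources=sources,
        partition=small_partition(),
        vaccine_prevalence={
            "pre_covid": 0.01, "pre_announcement": 0.04, "post_announcement": 0.07,
        },
        entity_plan={
            m: {"pre_covid": 0, "pre_announcement": p1, "post_announcement": p2}
            for m, p1, p2 in (
                ("astrazeneca", 5, 25), ("biontech", 2, 10),
                ("johnson & johnson", 2, 5), ("moderna", 4, 11),
                ("oxford", 7, 11), ("pfizer", 4, 30), ("sputnik v", 1, 3),
            )
        },
    )


@pytest.fixture(scope="session")
def small_corpus_truth():
    return generate(small_config())


@pytest.fixture(scope="session")
def small_corpus(small_corpus_truth):
    return small_corpus_truth[0]


@pytest.fixture(scope="session")
def small_truth(small_corpus_truth):
    return small_corpus_truth[1]


@pytest.fixture(scope="session")
def default_corpus_truth():
    """The full default-scale corpus (~29k records, Jul 2015 – Apr 2021)."""
    return generate(GeneratorConfig(seed=5))


@pytest.fixture(scope="session")
def tagged_small(small_corpus):
    from vaxpress.keywords import tag_corpus

    return tag_corpus(small_corpus)
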