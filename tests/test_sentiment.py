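"""Sentiment scoring, baselines, relative sentiment skew and
polarization summaries."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest

from vaxpress.corpus import Corpus, HeadlineRecord
from vaxpress.keywords import tag_corpus
from vaxpress.sentiment import (
    LexiconScorer,
    MissingBaselineError,
    NotEnglishError,
    RssValue,
    SentimentScore,
    compute_baselines,
    compute_rss,
    cumulative_rss_curve,
    polarization_proportions,
    score_corpus,
    score_headline,
)


def rec(title, source="s1", lang="en", day=1):
    return HeadlineRecord(
        source, "US", lang,
        datetime(2020, 6, day, tzinfo=timezone.utc), title,
    )


class TestSentimentScore:
    def test_raw_is_positive_minus_negative(self):
        s = SentimentScore(positive=0.5, negative=0.2, neutral=0.3, compound=0.4)
        assert s.raw == pytest.approx(0.3, abs=1e-12)

    def test_balanced_scores_give_zero_raw(self):
        assert SentimentScore(0.25, 0.25, 0.5, 0.0).raw == 0.0

    def test_all_neutral(self):
        assert SentimentScore(0.0, 0.0, 1.0, 0.0).raw == 0.0

    def test_mass_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SentimentScore(0.5, 0.5, 0.5, 0.0)


class TestLexiconScorer:
    def test_deterministic(self):
        s = LexiconScorer()
        a, b = s.score("good news for the city"), s.score("good news for the city")
        assert (a.positive, a.negative, a.compound) == (b.positive, b.negative,
                                                        b.compound)

    def test_known_valences(self):
        s = LexiconScorer().score("good bad")
        # good=+0.5, bad=-0.5 over 2 tokens
        assert s.positive == pytest.approx(0.25)
        assert s.negative == pytest.approx(0.25)
        assert s.raw == pytest.approx(0.0)

    def test_empty_text_is_neutral(self):
        s = LexiconScorer().score("")
        assert (s.positive, s.negative, s.neutral) == (0.0, 0.0, 1.0)

    def test_non_english_record_raises(self):
        with pytest.raises(NotEnglishError):
            score_headline(rec("gut", lang="de"), LexiconScorer())

    def test_score_corpus_skips_non_english(self):
        c = Corpus(records=[rec("fine day"), rec("bericht", lang="de")])
        scores = score_corpus(c, LexiconScorer())
        assert scores[0] is not None and scores[1] is None


def _scored_corpus(titles_by_source):
    """Build corpus + tags + scores from {source: [(title, vaccine)]}."""
    recs = []
    for source, items in titles_by_source.items():
        for title, vax in items:
            recs.append(rec(title + (" vaccine" if vax else ""), source=source))
    c = Corpus(records=recs)
    tags, _ = tag_corpus(c)
    scores = score_corpus(c, LexiconScorer())
    return c, tags, scores


class TestBaselines:
    def test_mean_of_two(self):
        # two non-topic headlines with known raws 0.1/2 and 0.3/2... use
        # direct construction instead: words at valence 0.2 and 0.6 over 2 tokens
        c, tags, scores = _scored_corpus(
            {"s1": [("helpful update", False), ("hopeful update", False),
                    ("good story", True)]}
        )
        base = compute_baselines(c, tags, scores, min_n=1)["s1"]
        raws = [s.raw for s, t in zip(scores, tags) if not t.vaccine]
        assert base.mean_raw == pytest.approx(np.mean(raws), abs=1e-15)
        assert base.n == 2

    def test_constant_scores_give_constant_mean(self):
        c, tags, scores = _scored_corpus(
            {"s1": [("fine update", False)] * 5 + [("good story", True)]}
        )
        base = compute_baselines(c, tags, scores, min_n=1)["s1"]
        assert base.mean_raw == pytest.approx(scores[0].raw, abs=1e-15)

    def test_equals_bruteforce_mean_on_random_fixture(self, small_corpus,
                                                      tagged_small):
        tags, _ = tagged_small
        scores = score_corpus(small_corpus, LexiconScorer())
        baselines = compute_baselines(small_corpus, tags, scores, min_n=1)
        for source_id, base in baselines.items():
            raws = [s.raw for r, t, s in zip(small_corpus, tags, scores)
                    if s is not None and not t.vaccine and r.source_id == source_id]
            assert base.mean_raw == pytest.approx(np.sum(raws) / len(raws),
                                                  abs=1e-12)
            assert base.n == len(raws)

    def test_min_n_flags_unreliable(self):
        c, tags, scores = _scored_corpus(
            {"s1": [("fine update", False), ("good story", True)]}
        )
        base = compute_baselines(c, tags, scores, min_n=30)["s1"]
        assert not base.reliable

    def test_missing_baseline_raises_in_rss(self):
        c, tags, scores = _scored_corpus({"s1": [("good story", True)]})
        with pytest.raises(MissingBaselineError):
            compute_rss(c, tags, scores, {})


class TestRss:
    def test_rss_arithmetic(self):
        c, tags, scores = _scored_corpus(
            {"s1": [("helpful update", False), ("hopeful update", False),
                    ("good news story", True)]}
        )
        baselines = compute_baselines(c, tags, scores, min_n=1)
        rss = compute_rss(c, tags, scores, baselines)
        topic_raw = [s.raw for s, t in zip(scores, tags) if t.vaccine][0]
        assert len(rss) == 1
        assert rss[0].rss_raw == pytest.approx(
            topic_raw - baselines["s1"].mean_raw, abs=1e-15)

    def test_identical_sentiment_gives_zero_rss(self):
        # equal-valence, equal-length titles: topic sentiment equals the
        # baseline exactly
        c = Corpus(records=[rec("good update story", source="s1")] * 4
                   + [rec("good update vaccine", source="s1")])
        tags, _ = tag_corpus(c)
        scores = score_corpus(c, LexiconScorer())
        baselines = compute_baselines(c, tags, scores, min_n=1)
        rss = compute_rss(c, tags, scores, baselines)
        assert rss[0].rss_raw == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance_is_exact(self, small_corpus, tagged_small):
        """Adding a constant to every score of a source cancels in RSS."""
        tags, _ = tagged_small
        scores = score_corpus(small_corpus, LexiconScorer())
        baselines = compute_baselines(small_corpus, tags, scores, min_n=1)
        rss = compute_rss(small_corpus, tags, scores, baselines)

        shift = 0.125  # exactly representable: no rounding noise allowed
        shifted = []
        for r, s in zip(small_corpus, scores):
            if s is None:
                shifted.append(None)
            else:
                shifted.append(_shifted_score(s, shift))
        base2 = compute_baselines(small_corpus, tags, shifted, min_n=1)
        rss2 = compute_rss(small_corpus, tags, shifted, base2)
        assert len(rss) == len(rss2) > 0
        for a, b in zip(rss, rss2):
            assert b.rss_raw == pytest.approx(a.rss_raw, abs=1e-12)

    def test_mean_rss_equals_mean_minus_baseline(self, small_corpus,
                                                 tagged_small):
        tags, _ = tagged_small
        scores = score_corpus(small_corpus, LexiconScorer())
        baselines = compute_baselines(small_corpus, tags, scores, min_n=1)
        rss = compute_rss(small_corpus, tags, scores, baselines)
        for source_id in {rv.record.source_id for rv in rss}:
            vals = [rv.rss_raw for rv in rss if rv.record.source_id == source_id]
            topic = [s.raw for r, t, s in zip(small_corpus, tags, scores)
                     if s is not None and t.vaccine and r.source_id == source_id]
            expect = np.mean(topic) - baselines[source_id].mean_raw
            assert np.mean(vals) == pytest.approx(expect, abs=1e-12)


def _shifted_score(s: SentimentScore, shift: float) -> SentimentScore:
    """Shift raw by `shift` keeping the mass constraint (moves positive
    mass up and neutral down)."""
    return SentimentScore(
        positive=s.positive + shift,
        negative=s.negative,
        neutral=s.neutral - shift,
        compound=min(1.0, s.compound + shift),
    )


def _rv(value, period="p1", source="s1"):
    return RssValue(rec("x", source=source), value, value, period)


class TestPolarization:
    def test_two_thirds_negative(self):
        table = polarization_proportions([_rv(-0.2), _rv(-0.1), _rv(0.3)])
        assert table.loc[0, "negative_fraction"] == pytest.approx(2 / 3)
        assert table.loc[0, "positive_fraction"] == pytest.approx(1 / 3)

    def test_all_positive(self):
        table = polarization_proportions([_rv(0.1), _rv(0.5)])
        assert table.loc[0, "negative_fraction"] == 0.0

    def test_zeros_excluded_and_counted(self):
        table = polarization_proportions([_rv(0.0), _rv(-1.0)])
        assert table.loc[0, "n_zero"] == 1
        assert table.loc[0, "negative_fraction"] == 1.0

    def test_fractions_sum_to_one(self):
        table = polarization_proportions(
            [_rv(v) for v in (-0.3, -0.2, 0.1, 0.4, 0.0)])
        row = table.loc[0]
        assert row["negative_fraction"] + row["positive_fraction"] == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            polarization_proportions([])

    def test_planted_shift_orders_negative_fractions(self):
        """Monte-Carlo: a negative topic shift yields majority-negative
        RSS, a positive shift majority-positive, at n=2000."""
        rng = np.random.default_rng(42)
        neg_topic = [_rv(v, period="A") for v in rng.normal(-0.05, 0.1, 2000)]
        pos_topic = [_rv(v, period="B") for v in rng.normal(+0.05, 0.1, 2000)]
        table = polarization_proportions(neg_topic + pos_topic)
        frac = dict(zip(table["group"], table["negative_fraction"]))
        assert frac["A"] > 0.5 > frac["B"]


class TestCumulativeCurve:
    def test_three_point_curve(self):
        table = cumulative_rss_curve([_rv(-1.0), _rv(0.0), _rv(1.0)])
        assert list(table["cumulative_fraction"]) == pytest.approx(
            [1 / 3, 2 / 3, 1.0])
        assert list(table["rss"]) == [-1.0, 0.0, 1.0]

    def test_singleton(self):
        table = cumulative_rss_curve([_rv(0.2)])
        assert list(table["cumulative_fraction"]) == [1.0]

    def test_matches_sort_based_ecdf_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0.02, 0.15, 500).round(3)
        table = cumulative_rss_curve([_rv(v) for v in values])
        # oracle: fraction of sample <= x at each distinct x
        for row in table.itertuples(index=False):
            assert row.cumulative_fraction == pytest.approx(
                np.mean(values <= row.rss), abs=1e-15)
        fracs = list(table["cumulative_fraction"])
        assert fracs == sorted(fracs)
        assert fracs[-1] == 1.0
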