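"""Entity canonicalization, counting, manufacturer subsets, and n-gram
tables with merge rules."""

from __future__ import annotations

from collections import Counter
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest

from vaxpress.corpus import Corpus, HeadlineRecord
from vaxpress.entities import (
    DictionaryNer,
    count_entities,
    extract_mentions,
    frequent_ngrams,
    manufacturer_subsets,
    merge_ngrams,
    normalize_entity,
)
from vaxpress.keywords import tag_corpus
from vaxpress.timeline import PeriodPartition


def rec(title, day=(2020, 6, 1), source="s1"):
    return HeadlineRecord(
        source, "US", "en",
        datetime(*day, tzinfo=timezone.utc), title,
    )


class TestNormalizeEntity:
    def test_partnership_split(self):
        assert normalize_entity("Pfizer-BioNTech") == ["pfizer", "biontech"]
        assert normalize_entity("AstraZeneca-Oxford") == ["astrazeneca", "oxford"]

    def test_johnson_aliases(self):
        assert normalize_entity("J&J") == ["johnson & johnson"]
        assert normalize_entity("Johnson and Johnson") == ["johnson & johnson"]

    def test_identity_casefold(self):
        assert normalize_entity("Moderna") == ["moderna"]

    def test_unknown_hyphen_pair_not_split(self):
        assert normalize_entity("Daily-Mail") == ["daily-mail"]

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError):
            normalize_entity("")


class TestDictionaryNer:
    def test_finds_multiword_and_hyphenated(self):
        hits = DictionaryNer().entities(
            "Pfizer-BioNTech shot cleared as Johnson & Johnson pauses")
        assert "pfizer-biontech" in hits
        assert "johnson & johnson" in hits

    def test_word_boundaries(self):
        assert DictionaryNer().entities("improved herd immunity") == []
        # "ema" must not fire inside other words
        assert DictionaryNer().entities("cinema reopens") == []


class TestCountEntities:
    def test_abbreviation_consolidation(self):
        mentions = ["fda"] * 5 + ["food and drug administration"] * 7
        table = count_entities(mentions)
        assert table.loc[0, "entity"] == "food and drug administration"
        assert table.loc[0, "count"] == 12
        assert "fda" not in set(table["entity"])

    def test_identity_without_abbreviations(self):
        table = count_entities(["moderna", "moderna", "oxford"])
        assert dict(zip(table["entity"], table["count"])) == {
            "moderna": 2, "oxford": 1}

    def test_nhs_not_consolidated(self):
        table = count_entities(["nhs", "nhs"])
        assert list(table["entity"]) == ["nhs"]

    def test_total_count_conserved(self):
        rng = np.random.default_rng(3)
        pool = ["fda", "cdc", "who", "moderna", "pfizer", "nhs",
                "world health organization"]
        mentions = list(rng.choice(pool, size=1000))
        table = count_entities(mentions)
        assert table["count"].sum() == 1000

    def test_matches_naive_tally_oracle(self):
        rng = np.random.default_rng(4)
        pool = ["moderna", "pfizer", "oxford", "nhs", "rdif"]
        mentions = list(rng.choice(pool, size=1000))
        table = count_entities(mentions)
        oracle = Counter(mentions)
        assert dict(zip(table["entity"], table["count"])) == dict(oracle)

    def test_deterministic_tie_order(self):
        table = count_entities(["b", "a", "c", "a", "c", "b"])
        assert list(table["entity"]) == ["a", "b", "c"]


class TestManufacturerSubsets:
    def _corpus(self):
        recs = [
            rec("AstraZeneca vaccine trial", day=(2020, 5, 1)),
            rec("AstraZeneca vaccine doubts", day=(2021, 1, 5)),
            rec("Pfizer-BioNTech vaccine approved", day=(2021, 1, 6)),
            rec("Moderna vaccine shipped", day=(2019, 7, 1)),
            rec("budget day"),
        ]
        c = Corpus(records=recs)
        tags, _ = tag_corpus(c)
        mentions = extract_mentions(t.record for t in tags if t.vaccine)
        return c, tags, mentions

    def test_matrix_counts_and_pandemic_total(self):
        c, tags, mentions = self._corpus()
        _, matrix = manufacturer_subsets(c, tags, mentions)
        az = matrix.loc["astrazeneca"]
        assert (az["pre_announcement"], az["post_announcement"]) == (1, 1)
        assert az["pandemic_total"] == 2
        assert matrix.loc["moderna", "pre_covid"] == 1

    def test_partnership_headline_joins_both_subsets(self):
        c, tags, mentions = self._corpus()
        subsets, _ = manufacturer_subsets(c, tags, mentions)
        pfizer = subsets[("pfizer", "post_announcement")]
        biontech = subsets[("biontech", "post_announcement")]
        assert pfizer == biontech
        assert "Pfizer-BioNTech" in pfizer[0].title

    def test_occurrence_counting_flag(self):
        c = Corpus(records=[rec("Pfizer and Pfizer again vaccine")])
        tags, _ = tag_corpus(c)
        mentions = extract_mentions(c)
        _, by_headline = manufacturer_subsets(c, tags, mentions)
        _, by_occurrence = manufacturer_subsets(
            c, tags, mentions, count_occurrences=True)
        assert by_headline.loc["pfizer", "pre_announcement"] == 1
        assert by_occurrence.loc["pfizer", "pre_announcement"] == 2

    def test_row_sums_match_reported_pandemic_mentions(self):
        """Period cells shaped like the study's manufacturer table sum to
        its quoted pandemic totals (747+5134=5881; 1010+2288=3298)."""
        cells = {"astrazeneca": (3, 747, 5134), "oxford": (3, 1010, 2288)}
        part = PeriodPartition()
        days = {"pre_covid": (2019, 7, 1), "pre_announcement": (2020, 5, 1),
                "post_announcement": (2021, 1, 5)}
        recs = []
        for manu, counts in cells.items():
            for period, k in zip(part.labels, counts):
                recs.extend(
                    rec(f"{manu.title()} vaccine story {i}", day=days[period])
                    for i in range(k)
                )
        c = Corpus(records=recs)
        tags, _ = tag_corpus(c)
        mentions = extract_mentions(c)
        _, matrix = manufacturer_subsets(c, tags, mentions)
        assert matrix.loc["astrazeneca", "pandemic_total"] == 5881
        assert matrix.loc["oxford", "pandemic_total"] == 3298


class TestNgrams:
    def test_enumeration_of_single_headline(self):
        table = frequent_ngrams([("food", "drug", "administr")])
        got = {tuple(g): c for g, c in zip(table["gram"], table["count"])}
        assert got == {
            ("food", "drug"): 1, ("drug", "administr"): 1,
            ("food", "drug", "administr"): 1,
        }

    def test_two_token_headline_has_no_trigram(self):
        table = frequent_ngrams([("blood", "clot")])
        assert set(table["n"]) == {2}

    def test_no_crossing_of_headline_boundaries(self):
        table = frequent_ngrams([("a", "b"), ("c", "d")])
        grams = {tuple(g) for g in table["gram"]}
        assert ("b", "c") not in grams

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(11)
        vocab = ["trial", "dose", "rollout", "blood", "clot", "approval"]
        seqs = [tuple(rng.choice(vocab, size=rng.integers(2, 7)))
                for _ in range(200)]
        table = frequent_ngrams(seqs, top_k=10_000)
        oracle: Counter = Counter()
        for s in seqs:
            for n in (2, 3):
                for i in range(len(s) - n + 1):
                    oracle[tuple(s[i:i + n])] += 1
        got = {tuple(g): c for g, c in zip(table["gram"], table["count"])}
        assert got == dict(oracle)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            frequent_ngrams([])


def _table(rows):
    return pd.DataFrame(
        [(tuple(g), len(g), c) for g, c in rows], columns=["gram", "n", "count"]
    )


class TestMergeNgrams:
    def test_equal_count_bigrams_removed(self):
        t = _table([(("food", "drug"), 10), (("drug", "administr"), 10),
                    (("food", "drug", "administr"), 10)])
        merged = merge_ngrams(t)
        assert [tuple(g) for g in merged["gram"]] == [
            ("food", "drug", "administr")]

    def test_differing_counts_retained(self):
        t = _table([(("food", "drug"), 15), (("food", "drug", "administr"), 10)])
        assert len(merge_ngrams(t)) == 2

    def test_tolerance_parameter(self):
        t = _table([(("food", "drug"), 11), (("food", "drug", "administr"), 10)])
        assert len(merge_ngrams(t, tolerance=1)) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        t = _random_table(rng)
        once = merge_ngrams(t)
        twice = merge_ngrams(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_matches_pairwise_containment_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            t = _random_table(rng)
            merged = merge_ngrams(t)
            kept = {(tuple(g), c) for g, c in zip(merged["gram"], merged["count"])}
            tris = [(tuple(g), c) for g, c in zip(t["gram"], t["count"])
                    if len(g) == 3]
            for g, c in zip(t["gram"], t["count"]):
                g = tuple(g)
                if len(g) == 3:
                    assert (g, c) in kept
                    continue
                drop = any(c == tc and (tri[:2] == g or tri[1:] == g)
                           for tri, tc in tris)
                assert ((g, c) in kept) == (not drop)


def _random_table(rng):
    vocab = ["food", "drug", "administr", "blood", "clot", "trial"]
    rows = []
    seen = set()
    for _ in range(rng.integers(5, 15)):
        n = int(rng.integers(2, 4))
        gram = tuple(rng.choice(vocab, size=n))
        if gram in seen:
            continue
        seen.add(gram)
        rows.append((gram, int(rng.integers(1, 5))))
    return _table(rows)
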