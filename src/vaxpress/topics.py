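"""Topic-model input preparation and the two-step cluster-count harness.

Vaccine headlines are cleaned for topic modeling: lemmatized, case-folded,
POS-filtered to content words, with links, outlet names, the word "news"
and every vaccine-extraction token (anything containing "vaccin",
"immuniz" or "immunis") removed — except "antivax"/"anti vax", which are
genuine topic signal.  Removing the extraction keywords prevents the topic
model from rediscovering the selection criterion as its dominant topic.

Cluster-count evaluation is a harness over a pluggable topic-model
backend: step 1 fits the backend at each candidate topic count and
profiles the resulting topics (sizes, top words, outlier fraction);
step 2 scores every topic pair's top-word overlap and flags pairs above a
review threshold as potential duplicates.  The harness reports; the final
choice of k is an operator decision, because seemingly different keyword
sets can describe the same subject and that judgement is manual.

The bundled backend clusters term-count vectors (scikit-learn
CountVectorizer + KMeans) and is deterministic under a fixed seed; a
transformer-based model such as BERTopic plugs in through the same
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np

from .corpus import HeadlineRecord
from .normalize import (
    CONTENT_POS,
    NormalizationProfile,
    TokenSequence,
    default_profiles,
    normalize,
    pos_filter,
    tag_tokens,
)

#: Substrings whose carrier tokens are removed from topic input.
REMOVE_SUBSTRINGS: tuple[str, ...] = ("vaccin", "immuniz", "immunis")
#: Tokens retained even though they would otherwise be removed/blocked.
RETAIN_TOKENS: frozenset[str] = frozenset({"antivax", "anti", "vax"})
#: Exact tokens always removed.
REMOVE_TOKENS: frozenset[str] = frozenset({"news"})


@dataclass(frozen=True)
class TopicInputDoc:
    """One cleaned, lemmatized document ready for topic modeling."""

    record: HeadlineRecord
    tokens: tuple[str, ...]

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def _clean_tokens(
    tokens: Iterable[str], source_names: frozenset[str]
) -> tuple[str, ...]:
    out = []
    for tok in tokens:
        if tok in RETAIN_TOKENS:
            out.append(tok)
            continue
        if tok in REMOVE_TOKENS or tok in source_names:
            continue
        if any(sub in tok for sub in REMOVE_SUBSTRINGS):
            continue
        out.append(tok)
    return tuple(out)


def prepare_topic_input(
    records: Iterable[HeadlineRecord],
    profile: NormalizationProfile | None = None,
    source_names: Iterable[str] = (),
    pos_keep: frozenset[str] = CONTENT_POS,
) -> tuple[list[TopicInputDoc], int]:
    """Clean vaccine headlines into topic-model input documents.

    Applies English lemmatization + case-folding, POS-filters to nouns
    (incl. proper nouns), verbs and adjectives, then removes outlet-name
    tokens (``source_names``, case-folded), the token "news", and every
    token containing a vaccine-extraction substring (keeping
    "antivax"/"anti vax").  Documents emptied by cleaning are dropped;
    returns ``(docs, n_dropped)``.  Deterministic and idempotent.
    """
    if profile is None:
        profile = default_profiles()["en"]
    names = frozenset(s.casefold() for s in source_names)
    docs: list[TopicInputDoc] = []
    dropped = 0
    for rec in records:
        if rec.language != "en":
            raise ValueError("topic input is English-only")
        tokens = normalize(rec.text, profile)
        if profile.tagger is not None:
            tokens = pos_filter(tag_tokens(tokens.tokens, profile), pos_keep)
        cleaned = _clean_tokens(tokens, names)
        if cleaned:
            docs.append(TopicInputDoc(rec, cleaned))
        else:
            dropped += 1
    return docs, dropped


# --------------------------------------------------------------------------
# Backend protocol and the bundled count-vector backend


@dataclass(frozen=True)
class TopicSet:
    """One fitted topic decomposition: k topics plus an outlier set."""

    k: int
    top_words: tuple[tuple[str, ...], ...]  # per topic, descending weight
    members: tuple[tuple[int, ...], ...]  # per topic, document indices
    outliers: tuple[int, ...] = ()

    def __post_init__(self):
        assigned = [i for topic in self.members for i in topic] + list(self.outliers)
        if len(assigned) != len(set(assigned)):
            raise ValueError("a document may belong to only one topic")

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(m) for m in self.members)

    @property
    def n_docs(self) -> int:
        return sum(self.sizes) + len(self.outliers)

    @property
    def outlier_fraction(self) -> float:
        return len(self.outliers) / self.n_docs if self.n_docs else 0.0


class TopicBackend(Protocol):
    def fit(self, docs: Sequence[str], k: int, seed: int) -> TopicSet: ...


class CountVectorBackend:
    """Term-count KMeans clustering backend.

    Documents become unit-normalized term-count vectors; KMeans with a
    fixed seed assigns each document to exactly one of k clusters (no
    outliers).  Top words per topic are ranked by summed within-cluster
    term count, ties broken alphabetically.
    """

    def __init__(self, top_n_words: int = 10, min_df: int = 1):
        self.top_n_words = top_n_words
        self.min_df = min_df

    def fit(self, docs: Sequence[str], k: int, seed: int) -> TopicSet:
        from sklearn.cluster import KMeans
        from sklearn.feature_extraction.text import CountVectorizer
        from sklearn.preprocessing import normalize as sk_normalize

        if len(docs) < k:
            raise ValueError(f"{len(docs)} documents cannot form {k} topics")
        vec = CountVectorizer(
            min_df=self.min_df, token_pattern=r"(?u)\b\w+\b", lowercase=True
        )
        X = vec.fit_transform(docs)
        Xn = sk_normalize(X, norm="l2")
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = km.fit_predict(Xn)
        vocab = np.array(vec.get_feature_names_out())

        members: list[tuple[int, ...]] = []
        top_words: list[tuple[str, ...]] = []
        for c in range(k):
            idx = np.flatnonzero(labels == c)
            members.append(tuple(int(i) for i in idx))
            if len(idx) == 0:
                top_words.append(())
                continue
            counts = np.asarray(X[idx].sum(axis=0)).ravel()
            order = np.lexsort((vocab, -counts))
            order = order[counts[order] > 0][: self.top_n_words]
            top_words.append(tuple(vocab[order]))
        return TopicSet(k=k, top_words=tuple(top_words), members=tuple(members))


# --------------------------------------------------------------------------
# Two-step evaluation


@dataclass(frozen=True)
class SimilarityFlag:
    """Top-word overlap between two topics of one fit."""

    pair: tuple[int, int]
    score: float  # |top-10 ∩ top-10| / 10, in [0, 1]
    verdict: str  # "distinct" or "review"


def topic_overlap(words_a: Sequence[str], words_b: Sequence[str], depth: int = 10) -> float:
    """Size of the intersection of the two top-``depth`` word sets,
    divided by ``depth``.  Symmetric; 1.0 for identical lists."""
    return len(set(words_a[:depth]) & set(words_b[:depth])) / depth


def similarity_flags(
    topic_set: TopicSet, threshold: float = 0.5, depth: int = 10
) -> list[SimilarityFlag]:
    """Pairwise overlap scores with a review verdict above ``threshold``."""
    flags = []
    for i in range(topic_set.k):
        for j in range(i + 1, topic_set.k):
            score = topic_overlap(topic_set.top_words[i], topic_set.top_words[j], depth)
            flags.append(
                SimilarityFlag(
                    pair=(i, j),
                    score=score,
                    verdict="review" if score >= threshold else "distinct",
                )
            )
    return flags


@dataclass
class CandidateReport:
    """Step-1 profile and step-2 flags for one candidate topic count."""

    k: int
    topic_set: TopicSet
    flags: list[SimilarityFlag] = field(default_factory=list)

    @property
    def n_review_pairs(self) -> int:
        return sum(1 for f in self.flags if f.verdict == "review")

    def summary(self) -> dict:
        return {
            "k": self.k,
            "sizes": list(self.topic_set.sizes),
            "outlier_fraction": self.topic_set.outlier_fraction,
            "n_review_pairs": self.n_review_pairs,
            "flagged_pairs": [
                {"pair": list(f.pair), "score": f.score}
                for f in self.flags
                if f.verdict == "review"
            ],
            "top_words": [list(w) for w in self.topic_set.top_words],
        }


def evaluate_cluster_counts(
    docs: Sequence[TopicInputDoc | str],
    candidates: Sequence[int],
    backend: TopicBackend | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    depth: int = 10,
) -> list[CandidateReport]:
    """Fit the backend at every candidate k and flag similar topic pairs.

    Step 1 fits and profiles each candidate; step 2 computes pairwise
    top-word overlap flags.  The returned reports support — but do not
    make — the final choice of k: a candidate above the true topic count
    typically shows review-flagged (near-duplicate) pairs, while the true
    count shows none.
    """
    if len(candidates) < 1:
        raise ValueError("at least one candidate topic count required")
    if not docs:
        raise ValueError("no documents")
    backend = backend or CountVectorBackend(top_n_words=depth)
    texts = [d.text if isinstance(d, TopicInputDoc) else d for d in docs]
    reports = []
    for k in sorted(set(candidates)):
        ts = backend.fit(texts, k, seed)
        reports.append(
            CandidateReport(k=k, topic_set=ts, flags=similarity_flags(ts, threshold, depth))
        )
    return reports
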