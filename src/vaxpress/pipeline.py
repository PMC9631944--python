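"""End-to-end analysis pipeline: simulate/load → tag → frequency →
sentiment → entities → n-grams → topics.

``run_all`` executes the stages in order against one corpus and writes
every result as a delimited table (plus JSON reports) into an output
directory.  Each table carries the pipeline config hash in a
``config_hash`` column, the full config is serialized alongside, and a
manifest records per-stage record counts (read, tagged, skipped), so
every output is auditable and re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import entities as ent
from . import keywords as kw
from . import sentiment as sent
from . import synthetic
from . import timeline as tl
from . import topics as tp
from .corpus import Corpus, read_corpus

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything ``run_all`` needs, serializable for provenance."""

    corpus_path: str | None = None  # None → simulate with `seed`
    out_dir: str = "vaxpress_out"
    seed: int = 0
    strict: bool = False
    dedup: bool = False
    baseline_scope: str = "all_periods"
    min_baseline_n: int = 30
    ngram_top_k: int = 50
    topic_candidates: tuple[int, ...] = (3, 5, 8)
    partition: tl.PeriodPartition = field(default_factory=tl.PeriodPartition)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (the output location
        does not change results and is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        payload = json.dumps(d, default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    df = df.copy()
    df["config_hash"] = cfg_hash
    df.to_csv(path, index=False)


def run_all(config: PipelineConfig, corpus: Corpus | None = None) -> Path:
    """Run every stage and write all tables; returns the output directory.

    A stage failure aborts the run with :class:`PipelineStageError`
    naming the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest: dict = {"config_hash": cfg_hash, "stages": {}}
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), default=str, indent=2)
    )

    def stage(name, fn):
        try:
            result = fn()
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %s done", name)
        return result

    def _corpus():
        if corpus is not None:
            c = corpus
        elif config.corpus_path is not None:
            c = read_corpus(config.corpus_path, strict=config.strict)
        else:
            c, truth = synthetic.generate(synthetic.GeneratorConfig(seed=config.seed))
            truth.to_csv(out / "ground_truth.csv", index=False)
        if config.dedup:
            c = c.deduplicate()
        manifest["stages"]["corpus"] = {"read": len(c), "skipped": c.skipped}
        return c

    c = stage("corpus", _corpus)

    def _tag():
        tags, summary = kw.tag_corpus(c)
        table = pd.DataFrame(
            {
                "source_id": [t.record.source_id for t in tags],
                "language": [t.record.language for t in tags],
                "timestamp": [t.record.timestamp.isoformat() for t in tags],
                "vaccine": [t.vaccine for t in tags],
                "covid": [t.covid for t in tags],
                "matched_terms": [" ".join(t.matched_terms) for t in tags],
            }
        )
        _write(table, out / "tags.csv", cfg_hash)
        (out / "tag_summary.json").write_text(
            json.dumps(
                {
                    "total": summary.total,
                    "vaccine": summary.vaccine,
                    "covid": summary.covid,
                    "by_language": summary.by_language,
                    "config_hash": cfg_hash,
                },
                indent=2,
            )
        )
        manifest["stages"]["tag"] = {
            "total": summary.total,
            "vaccine": summary.vaccine,
            "covid": summary.covid,
        }
        return tags

    tags = stage("tag", _tag)

    def _frequency():
        for topic in ("vaccine", "covid"):
            weekly = tl.weekly_relative_frequency(c, tags, topic=topic)
            _write(weekly, out / f"weekly_frequency_{topic}.csv", cfg_hash)
        by_country = tl.period_relative_frequency(
            c, tags, topic="vaccine", partition=config.partition
        )
        _write(by_country, out / "period_country_frequency.csv", cfg_hash)
        manifest["stages"]["frequency"] = {"rows": int(len(by_country))}

    stage("frequency", _frequency)

    def _sentiment():
        scorer = sent.LexiconScorer()
        scores = sent.score_corpus(c, scorer)
        baselines = sent.compute_baselines(
            c, tags, scores,
            scope=config.baseline_scope,
            partition=config.partition,
            min_n=config.min_baseline_n,
        )
        base_rows = pd.DataFrame(
            [
                {
                    "source_id": b.source_id,
                    "period": b.period or "",
                    "mean_raw": b.mean_raw,
                    "mean_compound": b.mean_compound,
                    "n": b.n,
                    "reliable": b.reliable,
                }
                for b in baselines.values()
            ]
        )
        _write(base_rows, out / "baselines.csv", cfg_hash)
        rss = sent.compute_rss(c, tags, scores, baselines,
                               partition=config.partition)
        rss_table = pd.DataFrame(
            {
                "source_id": [rv.record.source_id for rv in rss],
                "period": [rv.period for rv in rss],
                "rss_raw": [rv.rss_raw for rv in rss],
                "rss_compound": [rv.rss_compound for rv in rss],
            }
        )
        _write(rss_table, out / "rss.csv", cfg_hash)
        if rss:
            _write(sent.polarization_proportions(rss),
                   out / "polarization_rss.csv", cfg_hash)
            _write(sent.polarization_proportions(rss, measure="compound"),
                   out / "polarization_compound.csv", cfg_hash)
            _write(sent.cumulative_rss_curve(rss),
                   out / "cumulative_rss.csv", cfg_hash)
        manifest["stages"]["sentiment"] = {
            "scored": sum(s is not None for s in scores),
            "rss": len(rss),
            "baselines": len(baselines),
        }
        return scores, rss

    scores, rss = stage("sentiment", _sentiment)

    def _entities():
        vax_records = [t.record for t in tags if t.vaccine]
        mentions = ent.extract_mentions(vax_records)
        for label, pred in (("english", lambda r: r.language == "en"),
                            ("non_english", lambda r: r.language != "en")):
            sub = [m for m in mentions if pred(m.record)]
            if sub:
                _write(ent.count_entities(sub, top_k=30),
                       out / f"top_entities_{label}.csv", cfg_hash)
        subsets, matrix = ent.manufacturer_subsets(
            c, tags, mentions, partition=config.partition
        )
        _write(matrix.reset_index(), out / "manufacturer_counts.csv", cfg_hash)
        manifest["stages"]["entities"] = {"mentions": len(mentions)}
        return mentions, subsets

    mentions, subsets = stage("entities", _entities)

    def _ngrams():
        from .normalize import default_profiles, normalize

        profile = default_profiles()["en"]
        frames = []
        for (manu, period), recs in sorted(subsets.items()):
            en_recs = [r for r in recs if r.language == "en"]
            if not en_recs:
                continue
            seqs = [normalize(r.text, profile).tokens for r in en_recs]
            table = ent.merge_ngrams(
                ent.frequent_ngrams(seqs, top_k=config.ngram_top_k)
            )
            table.insert(0, "period", period)
            table.insert(0, "manufacturer", manu)
            table["gram"] = [" ".join(g) for g in table["gram"]]
            frames.append(table)
        if frames:
            _write(pd.concat(frames, ignore_index=True),
                   out / "manufacturer_ngrams.csv", cfg_hash)
        manifest["stages"]["ngrams"] = {"tables": len(frames)}

    stage("ngrams", _ngrams)

    def _topics():
        en_vax = [t.record for t in tags if t.vaccine and t.record.language == "en"]
        if len(en_vax) < max(config.topic_candidates):
            manifest["stages"]["topics"] = {"skipped": len(en_vax)}
            return
        docs, dropped = tp.prepare_topic_input(en_vax)
        reports = tp.evaluate_cluster_counts(
            docs, config.topic_candidates, seed=config.seed
        )
        (out / "topic_review.json").write_text(
            json.dumps(
                {
                    "config_hash": cfg_hash,
                    "n_docs": len(docs),
                    "n_dropped": dropped,
                    "candidates": [r.summary() for r in reports],
                },
                indent=2,
            )
        )
        rows = []
        for r in reports:
            for i, words in enumerate(r.topic_set.top_words):
                rows.append(
                    {
                        "k": r.k,
                        "topic": i,
                        "size": r.topic_set.sizes[i],
                        "top_words": " ".join(words),
                    }
                )
        _write(pd.DataFrame(rows), out / "topic_candidates.csv", cfg_hash)
        manifest["stages"]["topics"] = {"docs": len(docs), "dropped": dropped}

    stage("topics", _topics)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
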