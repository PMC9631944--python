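"""Headline corpus data model and JSON-lines I/O.

A corpus is a flat sequence of front-page headline records, one JSON object
per line (UTF-8, ISO-8601 timestamps).  Each record carries the six fields
needed downstream: the online news source (ONS) identifier, its country,
the headline language, the snapshot timestamp, the title and an optional
description.  Line-wise streaming keeps memory flat over large corpora.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: ISO-639-1 codes of the six supported headline languages.
SUPPORTED_LANGUAGES = frozenset({"en", "fr", "de", "it", "ru", "es"})

_FIELDS = ("source_id", "country", "language", "timestamp", "title", "description")


class CorpusError(ValueError):
    """Raised for malformed corpus files or records in strict mode."""


@dataclass(frozen=True)
class HeadlineRecord:
    """One front-page item from a single online news source.

    Parameters
    ----------
    source_id:
        Short identifier of the ONS the headline was scraped from.
    country:
        ISO-3166-like country code, or ``"INT"`` for internationally
        distributed sources.
    language:
        ISO-639-1 language code; must be one of :data:`SUPPORTED_LANGUAGES`.
    timestamp:
        Snapshot date-time; naive values are interpreted as UTC.
    title:
        Headline text, non-empty after stripping whitespace.
    description:
        Optional teaser/description text; may be empty.
    """

    source_id: str
    country: str
    language: str
    timestamp: datetime
    title: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.title.strip():
            raise CorpusError("headline title must be non-empty")
        if self.language not in SUPPORTED_LANGUAGES:
            raise CorpusError(f"unsupported language code: {self.language!r}")
        ts = self.timestamp
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        else:
            ts = ts.astimezone(timezone.utc)
        object.__setattr__(self, "timestamp", ts)

    @property
    def text(self) -> str:
        """Title and description joined with a single space."""
        return f"{self.title} {self.description}".strip()

    def to_json(self) -> str:
        d = {
            "source_id": self.source_id,
            "country": self.country,
            "language": self.language,
            "timestamp": self.timestamp.isoformat(),
            "title": self.title,
            "description": self.description,
        }
        return json.dumps(d, ensure_ascii=False)

    @classmethod
    def from_dict(cls, d: dict) -> "HeadlineRecord":
        missing = [k for k in _FIELDS if k != "description" and k not in d]
        if missing:
            raise CorpusError(f"record missing fields: {missing}")
        try:
            ts = datetime.fromisoformat(str(d["timestamp"]))
        except ValueError as exc:
            raise CorpusError(f"unparseable timestamp: {d['timestamp']!r}") from exc
        return cls(
            source_id=str(d["source_id"]),
            country=str(d["country"]),
            language=str(d["language"]),
            timestamp=ts,
            title=str(d["title"]),
            description=str(d.get("description", "")),
        )


@dataclass
class Corpus:
    """An ordered collection of :class:`HeadlineRecord` with provenance."""

    records: list[HeadlineRecord] = field(default_factory=list)
    provenance: str = ""
    skipped: int = 0  # invalid lines dropped during lenient parsing

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HeadlineRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Corpus) and self.records == other.records

    def by_source(self) -> dict[str, list[HeadlineRecord]]:
        """Partition records by ``source_id`` (preserving order)."""
        out: dict[str, list[HeadlineRecord]] = {}
        for r in self.records:
            out.setdefault(r.source_id, []).append(r)
        return out

    def subset(self, predicate) -> "Corpus":
        return Corpus(
            records=[r for r in self.records if predicate(r)],
            provenance=self.provenance,
        )

    def deduplicate(self) -> "Corpus":
        """Drop repeat snapshots of the same (source, title) pair.

        Front pages are re-scraped; the same headline can recur across
        snapshots.  Keeps the earliest occurrence.  Off by default in all
        pipelines.
        """
        seen: set[tuple[str, str]] = set()
        kept = []
        for r in sorted(self.records, key=lambda r: r.timestamp):
            key = (r.source_id, r.title)
            if key not in seen:
                seen.add(key)
                kept.append(r)
        return Corpus(records=kept, provenance=self.provenance)


def read_corpus(path: str | Path, strict: bool = False) -> Corpus:
    """Read a JSON-lines corpus file.

    In lenient mode (default) invalid lines are counted on
    ``Corpus.skipped`` and logged; in strict mode the first invalid line
    raises :class:`CorpusError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[HeadlineRecord] = []
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(HeadlineRecord.from_dict(json.loads(line)))
            except (json.JSONDecodeError, CorpusError) as exc:
                if strict:
                    raise CorpusError(f"{path}:{lineno}: {exc}") from exc
                skipped += 1
                logger.warning("skipping %s:%d: %s", path, lineno, exc)
    return Corpus(records=records, provenance=str(path), skipped=skipped)


def write_corpus(corpus: Corpus | Iterable[HeadlineRecord], path: str | Path) -> int:
    """Write records as JSON lines; returns the number written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(rec.to_json())
            fh.write("\n")
            n += 1
    return n
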