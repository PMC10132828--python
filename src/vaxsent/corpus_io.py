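"""Readers and writers for every on-disk artifact of the pipeline.

All formats are line-delimited UTF-8 text:

* tweet corpora — JSONL (one object per line) or 5-column TSV with fields
  ``id, created_at, author_id, lang, text``;
* keyword lists — one word per line;
* word-pair lists — two tab-separated words per line (used for the DCG
  embedding-fit criterion);
* label files — ``tweet_id<TAB>label`` with labels restricted to
  positive / negative / neutral;
* correction maps — ``misspelling<TAB>correction``.

The I/O layer never normalises or otherwise mutates text content; cleaning
is a separate, explicit stage.  Every reader/writer pair round-trips.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

SENTIMENT_LABELS = ("positive", "negative", "neutral")

TSV_FIELDS = ("id", "created_at", "author_id", "lang", "text")


class CorpusFormatError(ValueError):
    """Raised when a corpus file is mostly unparseable or a line-oriented
    artifact violates its format (e.g. a pair line without two fields)."""


@dataclass(frozen=True)
class TweetRecord:
    """One message: opaque id, UTC timestamp (second resolution), opaque
    author id, BCP-47-style language tag, raw text."""

    id: str
    created_at: datetime
    author_id: str
    lang: str
    text: str

    def __post_init__(self) -> None:
        if self.created_at.tzinfo is None:
            object.__setattr__(
                self, "created_at", self.created_at.replace(tzinfo=timezone.utc)
            )


@dataclass
class Corpus:
    """Ordered tweet stream plus a provenance trail (source path, filters
    applied, record counts).  Ordering is stable under write/read."""

    records: list[TweetRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _parse_timestamp(value: str) -> datetime:
    ts = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _format_timestamp(ts: datetime) -> str:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _record_from_json(line: str) -> TweetRecord:
    obj = json.loads(line)
    return TweetRecord(
        id=str(obj["id"]),
        created_at=_parse_timestamp(obj["created_at"]),
        author_id=str(obj["author_id"]),
        lang=str(obj["lang"]),
        text=str(obj["text"]),
    )


def _record_from_tsv(line: str) -> TweetRecord:
    parts = line.split("\t")
    if len(parts) != len(TSV_FIELDS):
        raise ValueError(f"expected {len(TSV_FIELDS)} fields, got {len(parts)}")
    rid, created, author, lang, text = parts
    return TweetRecord(
        id=rid,
        created_at=_parse_timestamp(created),
        author_id=author,
        lang=lang,
        text=text,
    )


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Load a corpus file; malformed lines are counted, reported in the
    provenance trail and via a warning.

    Raises
    ------
    FileNotFoundError
        if *path* does not exist.
    CorpusFormatError
        if more than half the non-empty lines are malformed.
    """
    path = Path(path)
    if format not in ("jsonl", "tsv"):
        raise ValueError(f"unknown corpus format: {format!r}")
    parse = _record_from_json if format == "jsonl" else _record_from_tsv

    records: list[TweetRecord] = []
    bad_lines: list[int] = []
    n_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            try:
                records.append(parse(line))
            except Exception:
                bad_lines.append(lineno)
    if n_lines and len(bad_lines) * 2 > n_lines:
        raise CorpusFormatError(
            f"{path}: {len(bad_lines)}/{n_lines} lines malformed "
            f"(lines {bad_lines[:20]}{'...' if len(bad_lines) > 20 else ''})"
        )
    if bad_lines:
        warnings.warn(
            f"{path}: skipped {len(bad_lines)} malformed line(s)", stacklevel=2
        )
    corpus = Corpus(records=records)
    corpus.provenance.append(
        f"read {len(records)} records from {path} ({format}); "
        f"malformed={len(bad_lines)}"
    )
    return corpus


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus in JSONL or TSV.  TSV replaces embedded tabs/newlines
    in the text field with spaces (the only lossy case)."""
    path = Path(path)
    if format not in ("jsonl", "tsv"):
        raise ValueError(f"unknown corpus format: {format!r}")
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus.records:
            if format == "jsonl":
                obj = {
                    "id": rec.id,
                    "created_at": _format_timestamp(rec.created_at),
                    "author_id": rec.author_id,
                    "lang": rec.lang,
                    "text": rec.text,
                }
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
            else:
                text = rec.text.replace("\t", " ").replace("\n", " ")
                fh.write(
                    "\t".join(
                        (
                            rec.id,
                            _format_timestamp(rec.created_at),
                            rec.author_id,
                            rec.lang,
                            text,
                        )
                    )
                    + "\n"
                )


def corpus_file_stats(path: str | Path, format: str = "jsonl") -> dict:
    """Validation summary for a corpus file: total / well-formed / malformed
    line counts and the malformed line numbers."""
    path = Path(path)
    parse = _record_from_json if format == "jsonl" else _record_from_tsv
    ok = 0
    bad: list[int] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                parse(line)
                ok += 1
            except Exception:
                bad.append(lineno)
    return {
        "path": str(path),
        "format": format,
        "well_formed": ok,
        "malformed": len(bad),
        "malformed_lines": bad,
    }


def read_keywords(path: str | Path) -> list[str]:
    """One keyword per line; order preserved; duplicates removed with a
    warning."""
    seen: dict[str, None] = {}
    dupes = 0
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            word = line.strip()
            if not word:
                continue
            if word in seen:
                dupes += 1
            else:
                seen[word] = None
    if dupes:
        warnings.warn(f"{path}: dropped {dupes} duplicate keyword(s)", stacklevel=2)
    return list(seen)


def write_keywords(words: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for w in words:
            fh.write(w + "\n")


def read_word_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Tab-separated pair list used to score embedding fit.

    Raises :class:`CorpusFormatError` for a line without exactly two fields
    or a pair whose two words are identical.
    """
    pairs: list[tuple[str, str]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: pair line needs exactly 2 tab-separated "
                    f"fields, got {len(parts)}"
                )
            a, b = (p.strip() for p in parts)
            if a == b:
                raise CorpusFormatError(
                    f"{path}:{lineno}: pair words must differ ({a!r})"
                )
            pairs.append((a, b))
    return pairs


def write_word_pairs(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Label TSV ``tweet_id<TAB>label``; labels restricted to
    positive/negative/neutral."""
    labels: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: label line needs id and label"
                )
            tid, label = parts[0], parts[1]
            if label not in SENTIMENT_LABELS:
                raise CorpusFormatError(
                    f"{path}:{lineno}: unknown label {label!r} "
                    f"(expected one of {SENTIMENT_LABELS})"
                )
            labels[tid] = label
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for tid, label in labels.items():
            fh.write(f"{tid}\t{label}\n")


def read_correction_map(path: str | Path) -> dict[str, str]:
    """2-column TSV ``misspelling<TAB>correction`` (human-editable so curated
    dictionaries can grow beyond the automatically built entries)."""
    entries: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: correction line needs exactly 2 fields"
                )
            entries[parts[0]] = parts[1]
    return entries


def write_correction_map(entries: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for wrong, right in entries.items():
            fh.write(f"{wrong}\t{right}\n")
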