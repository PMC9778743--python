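"""Timestamped short-text documents and their file readers.

Documents arrive as JSON-lines (one tweet-like record per line) or CSV.
Field aliases follow the common tweet-export conventions: ``id``/``id_str``,
``created_at``/``timestamp``, ``text``/``full_text``.
"""
from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator
from zoneinfo import ZoneInfo

from .errors import EmovarError

__all__ = ["Document", "read_documents", "filter_documents", "document_date"]


@dataclass(frozen=True)
class Document:
    """One short text with a timestamp and optional language/country tags."""

    id: str
    timestamp: dt.date | dt.datetime | str
    text: str
    lang: str | None = None
    country_code: str | None = None

    def __post_init__(self):
        if not self.id:
            raise EmovarError("document id must be nonempty")


def document_date(doc: Document, tz: str = "UTC") -> dt.date:
    """Calendar date of a document under a fixed named timezone.

    Naive timestamps are interpreted as already being in ``tz``.
    """
    ts = doc.timestamp
    if isinstance(ts, str):
        ts = _parse_timestamp(ts)
    if isinstance(ts, dt.datetime):
        if ts.tzinfo is not None:
            ts = ts.astimezone(ZoneInfo(tz))
        return ts.date()
    if isinstance(ts, dt.date):
        return ts
    raise EmovarError(f"unparseable timestamp on document {doc.id!r}: {doc.timestamp!r}")


_TS_FORMATS = (
    "%a %b %d %H:%M:%S %z %Y",  # classic tweet format
    "%Y-%m-%dT%H:%M:%S%z",
    "%Y-%m-%d %H:%M:%S",
    "%Y-%m-%dT%H:%M:%S",
    "%Y-%m-%d",
)


def _parse_timestamp(raw: str) -> dt.datetime | dt.date:
    raw = raw.strip()
    for fmt in _TS_FORMATS:
        try:
            parsed = dt.datetime.strptime(raw, fmt)
        except ValueError:
            continue
        if fmt == "%Y-%m-%d":
            return parsed.date()
        return parsed
    try:  # ISO with fractional seconds or offsets the formats above miss
        return dt.datetime.fromisoformat(raw)
    except ValueError:
        raise EmovarError(f"unparseable timestamp: {raw!r}") from None


def _record_to_document(rec: dict) -> Document:
    doc_id = rec.get("id") or rec.get("id_str")
    if doc_id is None:
        raise EmovarError(f"record missing id/id_str: {rec!r}")
    ts = rec.get("created_at") or rec.get("timestamp")
    if ts is None:
        raise EmovarError(f"record {doc_id!r} missing created_at/timestamp")
    text = rec.get("text")
    if text is None:
        text = rec.get("full_text")
    if text is None:
        raise EmovarError(f"record {doc_id!r} missing text/full_text")
    lang = rec.get("lang") or None
    country = rec.get("country_code") or None
    return Document(
        id=str(doc_id), timestamp=str(ts), text=str(text),
        lang=str(lang) if lang else None,
        country_code=str(country) if country else None,
    )


def read_documents(path: str | Path) -> Iterator[Document]:
    """Stream documents from a JSON-lines (``.jsonl``/``.json``) or CSV file."""
    path = Path(path)
    if not path.exists():
        raise EmovarError(f"documents file not found: {path}")
    if path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                yield _record_to_document(rec)
    else:
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield _record_to_document(json.loads(line))


def filter_documents(
    docs: Iterable[Document],
    country: str | None = None,
    lang: str | None = None,
    date_from: dt.date | None = None,
    date_to: dt.date | None = None,
    tz: str = "UTC",
) -> Iterator[Document]:
    """Keep documents matching the country/language tags and date window.

    Documents missing a tag that is being filtered on are dropped,
    mirroring the convention of location-tagged corpus studies.
    """
    for doc in docs:
        if country is not None and doc.country_code != country:
            continue
        if lang is not None and doc.lang != lang:
            continue
        if date_from is not None or date_to is not None:
            d = document_date(doc, tz=tz)
            if date_from is not None and d < date_from:
                continue
            if date_to is not None and d > date_to:
                continue
        yield doc
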