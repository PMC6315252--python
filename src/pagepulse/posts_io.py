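"""Post data model and table I/O.

A *post* is one publication on a Facebook page together with its public
interaction counts (reactions, shares, comments) and, when exported by a
page administrator, the private metrics clicks, reach and hides. Posts are
exchanged as CSV or JSON tables with a fixed column set; absent optional
counts are serialized as empty cells, never as zeros, because "reach
unavailable" and "reach = 0" mean different things for the engagement rate.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, fields
from datetime import datetime
from pathlib import Path
from typing import Iterator, Optional
from zoneinfo import ZoneInfo

#: Facebook's five publication formats.
POST_TYPES = frozenset({"photo", "video", "event", "status", "link"})

#: Default local zone for naive timestamps (the corpora are Brazilian pages).
DEFAULT_TIMEZONE = "America/Sao_Paulo"

#: Fixed column order for tabular interchange.
COLUMNS = [
    "post_id",
    "page_id",
    "group",
    "timestamp",
    "post_type",
    "text",
    "reactions",
    "shares",
    "comments",
    "clicks",
    "reach",
    "hides",
    "manual_category",
]

REQUIRED_COLUMNS = COLUMNS[:9]
OPTIONAL_COUNTS = ("clicks", "reach", "hides")


class SchemaError(ValueError):
    """A post table is missing a required column or is malformed."""


class PostValidationError(ValueError):
    """A post record violates a field constraint."""


@dataclass
class Post:
    """One page publication with its interaction counts.

    ``clicks``, ``reach`` and ``hides`` are administrator-only metrics and
    are ``None`` when the data came from public monitoring; ``manual_category``
    holds a human coder's label when available.
    """

    post_id: str
    page_id: str
    group: str
    timestamp: datetime
    post_type: str
    text: str
    reactions: int
    shares: int
    comments: int
    clicks: Optional[int] = None
    reach: Optional[int] = None
    hides: Optional[int] = None
    manual_category: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.post_id:
            raise PostValidationError("post_id must be non-empty")
        if self.post_type not in POST_TYPES:
            raise PostValidationError(
                f"post {self.post_id!r}: unknown post_type {self.post_type!r}; "
                f"expected one of {sorted(POST_TYPES)}"
            )
        for name in ("reactions", "shares", "comments"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise PostValidationError(
                    f"post {self.post_id!r}: {name} must be a non-negative integer, got {value!r}"
                )
        for name in OPTIONAL_COUNTS:
            value = getattr(self, name)
            if value is not None and (not isinstance(value, int) or value < 0):
                raise PostValidationError(
                    f"post {self.post_id!r}: {name} must be a non-negative integer when present, got {value!r}"
                )
        if not isinstance(self.timestamp, datetime) or self.timestamp.tzinfo is None:
            raise PostValidationError(
                f"post {self.post_id!r}: timestamp must be timezone-aware"
            )


@dataclass
class Corpus:
    """An ordered collection of posts with unique ids."""

    posts: list[Post] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for post in self.posts:
            if post.post_id in seen:
                raise PostValidationError(f"duplicate post_id {post.post_id!r}")
            seen.add(post.post_id)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def __getitem__(self, i):
        return self.posts[i]

    def ids(self) -> list[str]:
        return [p.post_id for p in self.posts]

    def to_frame(self):
        """Return the corpus as a pandas DataFrame in interchange column order."""
        import pandas as pd

        return pd.DataFrame(
            [{c: getattr(p, c) for c in COLUMNS} for p in self.posts],
            columns=COLUMNS,
        )


def _parse_timestamp(raw: str, default_tz: str) -> datetime:
    ts = datetime.fromisoformat(raw)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=ZoneInfo(default_tz))
    return ts


def _parse_optional_int(raw, column: str, post_id: str) -> Optional[int]:
    if raw is None or raw == "":
        return None
    try:
        value = int(raw)
    except (TypeError, ValueError):
        raise PostValidationError(
            f"post {post_id!r}: {column} is not an integer: {raw!r}"
        ) from None
    return value


def _post_from_record(rec: dict, default_tz: str) -> Post:
    post_id = str(rec.get("post_id", ""))
    try:
        timestamp = _parse_timestamp(str(rec["timestamp"]), default_tz)
    except ValueError:
        raise PostValidationError(
            f"post {post_id!r}: unparseable timestamp {rec['timestamp']!r}"
        ) from None
    kwargs = {
        "post_id": post_id,
        "page_id": str(rec["page_id"]),
        "group": str(rec["group"]),
        "timestamp": timestamp,
        "post_type": str(rec["post_type"]),
        "text": "" if rec.get("text") is None else str(rec["text"]),
    }
    for name in ("reactions", "shares", "comments"):
        value = _parse_optional_int(rec.get(name), name, post_id)
        if value is None:
            raise PostValidationError(f"post {post_id!r}: {name} is required")
        kwargs[name] = value
    for name in OPTIONAL_COUNTS:
        kwargs[name] = _parse_optional_int(rec.get(name), name, post_id)
    manual = rec.get("manual_category")
    kwargs["manual_category"] = None if manual in (None, "") else str(manual)
    return Post(**kwargs)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_posts(path, format: Optional[str] = None, default_tz: str = DEFAULT_TIMEZONE) -> Corpus:
    """Read a post table from CSV or JSON.

    Naive timestamps are interpreted in ``default_tz``. Empty optional cells
    become absent fields (``None``), not zeros.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in REQUIRED_COLUMNS if c not in header]
            if missing:
                raise SchemaError(
                    f"{path.name}: missing required column(s): {', '.join(missing)}"
                )
            posts = [_post_from_record(row, default_tz) for row in reader]
        provenance = f"csv:{path.name}"
    else:
        with path.open(encoding="utf-8") as fh:
            payload = json.load(fh)
        if isinstance(payload, dict):
            records = payload.get("posts", [])
            provenance = payload.get("provenance", f"json:{path.name}")
        else:
            records = payload
            provenance = f"json:{path.name}"
        posts = []
        for rec in records:
            missing = [c for c in REQUIRED_COLUMNS if c not in rec]
            if missing:
                raise SchemaError(
                    f"{path.name}: record missing required field(s): {', '.join(missing)}"
                )
            posts.append(_post_from_record(rec, default_tz))
    return Corpus(posts=posts, provenance=provenance)


def _record_for_write(post: Post) -> dict:
    rec = {}
    for name in COLUMNS:
        value = getattr(post, name)
        if name == "timestamp":
            value = value.isoformat()
        rec[name] = value
    return rec


def write_posts(corpus: Corpus, path, format: Optional[str] = None) -> None:
    """Write a corpus so that :func:`read_posts` reproduces it field-for-field."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=COLUMNS, lineterminator="\n")
            writer.writeheader()
            for post in corpus:
                rec = _record_for_write(post)
                writer.writerow({k: ("" if v is None else v) for k, v in rec.items()})
    else:
        records = []
        for post in corpus:
            rec = _record_for_write(post)
            records.append({k: v for k, v in rec.items() if v is not None})
        payload = {"provenance": corpus.provenance, "posts": records}
        with path.open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=1)
            fh.write("\n")
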