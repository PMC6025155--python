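"""Posts and corpora: the labeled narrative documents the pipeline consumes.

A post carries an id, a set of whitespace-free labels, optional background
and topic tags, a caption (metadata text) and a narrative body.  Corpora
round-trip through CSV (RFC-4180 quoting) and JSON-Lines; spelling
irregularities in the body are preserved verbatim — normalization is the
text pipeline's job.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

DEFAULT_FIELD_MAP = {
    "id": "id",
    "label": "label",
    "text": "text",
    "caption": "caption",
    "background": "background",
    "topic": "topic",
}


class CorpusError(ValueError):
    """Malformed corpus input."""


@dataclass
class Post:
    id: str
    labels: set[str] = field(default_factory=set)
    background: set[str] = field(default_factory=set)
    topics: set[str] = field(default_factory=set)
    caption: str = ""
    text: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("post id must be non-empty")
        if not self.text and not self.caption:
            raise CorpusError(f"post {self.id!r}: text and caption both empty")

    def canonical(self) -> dict:
        return {
            "id": self.id,
            "labels": sorted(unicodedata.normalize("NFC", s) for s in self.labels),
            "background": sorted(
                unicodedata.normalize("NFC", s) for s in self.background
            ),
            "topics": sorted(unicodedata.normalize("NFC", s) for s in self.topics),
            "caption": unicodedata.normalize("NFC", self.caption),
            "text": unicodedata.normalize("NFC", self.text),
            "attributes": {
                k: unicodedata.normalize("NFC", v)
                for k, v in sorted(self.attributes.items())
            },
        }


@dataclass
class Corpus:
    posts: list[Post] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for post in self.posts:
            if post.id in seen:
                raise CorpusError(f"duplicate post id {post.id!r}")
            seen.add(post.id)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self):
        return iter(self.posts)

    def canonical(self) -> list[dict]:
        return [p.canonical() for p in self.posts]


def _post_from_record(
    record: dict, field_map: dict[str, str], where: str
) -> Post:
    def get(key: str, required: bool = False):
        col = field_map.get(key, DEFAULT_FIELD_MAP.get(key))
        if col is None or col not in record:
            if required:
                raise CorpusError(f"{where}: missing mapped column {col or key!r}")
            return None
        return record[col]

    raw_id = get("id", required=True)
    raw_label = get("label", required=True)
    raw_text = get("text", required=True)

    def as_set(value) -> set[str]:
        if value is None or value == "":
            return set()
        if isinstance(value, (list, tuple, set)):
            return {str(v) for v in value}
        return set(str(value).split())

    attributes = record.get("attributes") or {}
    if isinstance(attributes, str):
        attributes = json.loads(attributes) if attributes else {}
    return Post(
        id=str(raw_id),
        labels=as_set(raw_label),
        background=as_set(get("background")),
        topics=as_set(get("topic")),
        caption=str(get("caption") or ""),
        text=str(raw_text or ""),
        attributes={str(k): str(v) for k, v in attributes.items()},
    )


def read_corpus(
    path: str, format: str = "csv", field_map: dict[str, str] | None = None
) -> Corpus:
    """Read a corpus; ``field_map`` maps canonical field names (id, label,
    text, caption, background, topic) to column/key names in the file.

    Label fields are split on whitespace into label sets.  Duplicate ids
    and missing mapped columns are errors.
    """
    field_map = {**DEFAULT_FIELD_MAP, **(field_map or {})}
    posts: list[Post] = []
    if format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):
                posts.append(_post_from_record(row, field_map, f"{path}:{i}"))
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                posts.append(
                    _post_from_record(json.loads(line), field_map, f"{path}:{i}")
                )
    else:
        raise CorpusError(f"unknown corpus format {format!r}")
    return Corpus(posts=posts)


_CSV_COLUMNS = ("id", "label", "background", "topic", "caption", "text", "attributes")


def write_corpus(corpus: Corpus, path: str, format: str = "csv") -> None:
    if format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for post in corpus:
                writer.writerow(
                    (
                        post.id,
                        " ".join(sorted(post.labels)),
                        " ".join(sorted(post.background)),
                        " ".join(sorted(post.topics)),
                        post.caption,
                        post.text,
                        json.dumps(post.attributes, sort_keys=True)
                        if post.attributes
                        else "",
                    )
                )
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for post in corpus:
                fh.write(
                    json.dumps(
                        {
                            "id": post.id,
                            "label": sorted(post.labels),
                            "background": sorted(post.background),
                            "topic": sorted(post.topics),
                            "caption": post.caption,
                            "text": post.text,
                            "attributes": dict(sorted(post.attributes.items())),
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        raise CorpusError(f"unknown corpus format {format!r}")


def load_example_posts() -> Corpus:
    """The five packaged example posts (one per drug label)."""
    path = resources.files("kitm.data").joinpath("table2_posts.csv")
    with resources.as_file(path) as p:
        return read_corpus(str(p), format="csv")
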