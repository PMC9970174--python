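"""Document and corpus containers plus readers/writers for the interchange formats.

A corpus is an ordered collection of de-identified clinical documents, each
labelled with the study arm it belongs to (pre- or post-intervention).
Consumer names are assumed to have been replaced upstream by the placeholder
token ``CNAME``; no de-identification happens here.

The canonical interchange format is JSONL — one document per line with keys
``doc_id``, ``arm``, optional ``author_id`` and ``text``. CSV (same columns)
and a directory of ``.txt`` files with a ``manifest.csv`` are accepted as
convenience dialects.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    DuplicateIdError,
    EmptyCorpusError,
    SchemaError,
)

__all__ = [
    "Arm",
    "RawDocument",
    "Corpus",
    "read_corpus",
    "write_corpus",
    "write_table",
]


class Arm(str, Enum):
    """Study arm of a document: before or after the training intervention."""

    PRE = "pre"
    POST = "post"

    @classmethod
    def parse(cls, value: str) -> "Arm":
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise SchemaError(
                f"unknown arm label {value!r}; expected 'pre' or 'post'"
            ) from None


@dataclass(frozen=True)
class RawDocument:
    """One de-identified clinical document (e.g. a care review summary)."""

    doc_id: str
    arm: Arm
    text: str
    author_id: str | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise SchemaError("doc_id must be non-empty")
        if not self.text.strip():
            raise SchemaError(f"document {self.doc_id!r} has empty text")


@dataclass
class Corpus:
    """An ordered, id-unique collection of raw documents."""

    documents: list[RawDocument] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.documents:
            raise EmptyCorpusError("corpus contains zero documents")
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise DuplicateIdError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]


def _doc_from_record(rec: Mapping[str, object], source: str) -> RawDocument:
    missing = {"doc_id", "arm", "text"} - set(rec)
    if missing:
        raise SchemaError(f"{source}: record missing fields {sorted(missing)}")
    author = rec.get("author_id")
    if author is not None and (author == "" or (isinstance(author, float) and pd.isna(author))):
        author = None
    return RawDocument(
        doc_id=str(rec["doc_id"]),
        arm=Arm.parse(str(rec["arm"])),
        text=str(rec["text"]),
        author_id=None if author is None else str(author),
    )


def _read_jsonl(path: Path) -> list[RawDocument]:
    docs = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: invalid JSON ({exc})") from None
            docs.append(_doc_from_record(rec, f"{path}:{lineno}"))
    return docs


def _read_csv(path: Path) -> list[RawDocument]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty and frame.columns.empty:
        return []
    required = {"doc_id", "arm", "text"}
    if not required <= set(frame.columns):
        raise SchemaError(
            f"{path}: CSV must have columns doc_id, arm, text; got {list(frame.columns)}"
        )
    return [_doc_from_record(row, str(path)) for row in frame.to_dict(orient="records")]


def _read_txt_dir(path: Path) -> list[RawDocument]:
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise SchemaError(f"{path}: txt_dir format requires a manifest.csv")
    docs = []
    with manifest.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "filename" not in reader.fieldnames or "arm" not in reader.fieldnames:
            raise SchemaError(f"{manifest}: manifest needs columns filename, arm")
        for row in reader:
            fname = row["filename"]
            text = (path / fname).read_text(encoding="utf-8")
            docs.append(
                RawDocument(
                    doc_id=row.get("doc_id") or Path(fname).stem,
                    arm=Arm.parse(row["arm"]),
                    text=text,
                    author_id=row.get("author_id") or None,
                )
            )
    return docs


_READERS = {"jsonl": _read_jsonl, "csv": _read_csv, "txt_dir": _read_txt_dir}


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus, preserving document order exactly as stored.

    Parameters
    ----------
    path:
        File (jsonl/csv) or directory (txt_dir) to read.
    format:
        One of ``jsonl``, ``csv``, ``txt_dir``. When omitted it is inferred
        from the path (directory -> txt_dir, else by extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir():
            format = "txt_dir"
        elif path.suffix.lower() == ".csv":
            format = "csv"
        else:
            format = "jsonl"
    try:
        reader = _READERS[format]
    except KeyError:
        raise SchemaError(f"unknown corpus format {format!r}") from None
    docs = reader(path)
    if not docs:
        raise EmptyCorpusError(f"{path}: no documents found")
    return Corpus(docs)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL (the canonical, byte-stable interchange form)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            rec = {"doc_id": doc.doc_id, "arm": doc.arm.value, "text": doc.text}
            if doc.author_id is not None:
                rec["author_id"] = doc.author_id
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_table(
    rows: Sequence[Mapping[str, object]] | Iterable[Mapping[str, object]],
    path: str | Path,
    key: str | Sequence[str] | None = None,
    columns: Sequence[str] | None = None,
) -> None:
    """Write result records as a UTF-8 CSV with a deterministic row order.

    All rows must share one header schema; floats are rendered with six
    significant digits. ``key`` names the column(s) the table is sorted by;
    without a key the input order is kept.
    """
    rows = list(rows)
    if rows:
        header = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != header:
                raise SchemaError(
                    f"row fields {list(r.keys())} do not match header {header}"
                )
        frame = pd.DataFrame(rows, columns=header)
    else:
        frame = pd.DataFrame(columns=list(columns) if columns else [])
    if key is not None and not frame.empty:
        frame = frame.sort_values(by=key, kind="stable")
    frame.to_csv(path, index=False, float_format="%.6g")
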