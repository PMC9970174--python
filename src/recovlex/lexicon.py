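"""The category dictionary: 1-3 token terms, each in exactly one language category.

Three categories are distinguished: recovery-oriented rehabilitation language
(REHAB), person-centred language that is not also rehabilitation-focused
(PERSON), and pejorative language (PEJ). Terms are literal ngrams — contiguous
token sequences with no gaps and no stemming — and may contain the ``cname``
placeholder standing for a de-identified consumer name.

File format: UTF-8 CSV with header ``term,category,source``; terms hold
space-separated tokens, the placeholder spelled CNAME in files, and category
one of rehab / person / pejorative (case-insensitive).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import (
    DisjointCategoryError,
    EmptyLexiconError,
    SchemaError,
    TermLengthError,
)

__all__ = [
    "Category",
    "LexiconEntry",
    "Lexicon",
    "load_lexicon",
    "save_lexicon",
    "bundled_example_lexicon",
]

MAX_TERM_TOKENS = 3


class Category(str, Enum):
    REHAB = "rehab"
    PERSON = "person"
    PEJ = "pejorative"

    @classmethod
    def parse(cls, value: str) -> "Category":
        norm = str(value).strip().lower()
        aliases = {"pej": "pejorative"}
        norm = aliases.get(norm, norm)
        try:
            return cls(norm)
        except ValueError:
            raise SchemaError(
                f"unknown category {value!r}; expected rehab, person or pejorative"
            ) from None


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary term: an ordered 1-3 token ngram with its category."""

    term_tokens: tuple[str, ...]
    category: Category
    source: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.term_tokens) <= MAX_TERM_TOKENS:
            raise TermLengthError(
                f"term {' '.join(self.term_tokens)!r} has {len(self.term_tokens)} tokens; "
                f"allowed range is 1-{MAX_TERM_TOKENS}"
            )
        for tok in self.term_tokens:
            if not tok or any(ch.isspace() for ch in tok):
                raise SchemaError(f"invalid token {tok!r} in term {self.term_tokens}")

    @property
    def term(self) -> str:
        return " ".join(self.term_tokens)


def _normalize_term(term: str) -> tuple[str, ...]:
    tokens = tuple(t.lower() for t in str(term).split())
    if not tokens:
        raise SchemaError("empty term")
    return tokens


@dataclass
class Lexicon:
    """A validated collection of terms with disjoint categories."""

    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_tokens: dict[tuple[str, ...], LexiconEntry] = {}
        for entry in self.entries:
            if entry.term_tokens in by_tokens:
                raise DisjointCategoryError(
                    f"term {entry.term!r} appears more than once "
                    f"({by_tokens[entry.term_tokens].category.value} and {entry.category.value})"
                )
            by_tokens[entry.term_tokens] = entry
        self._by_tokens = by_tokens

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterable[LexiconEntry]:
        return iter(self.entries)

    def __contains__(self, term) -> bool:
        return self._key(term) in self._by_tokens

    @staticmethod
    def _key(term) -> tuple[str, ...]:
        if isinstance(term, str):
            return _normalize_term(term)
        return tuple(term)

    def lookup(self, term) -> LexiconEntry | None:
        """Entry for a term given as a string ("cname will") or token tuple."""
        return self._by_tokens.get(self._key(term))

    def category_of(self, term) -> Category:
        entry = self.lookup(term)
        if entry is None:
            raise KeyError(term)
        return entry.category

    def terms_of(self, category: Category) -> list[LexiconEntry]:
        return [e for e in self.entries if e.category == category]

    @property
    def by_tokens(self) -> dict[tuple[str, ...], LexiconEntry]:
        return dict(self._by_tokens)

    def token_vocabulary(self) -> set[str]:
        return {tok for e in self.entries for tok in e.term_tokens}


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon CSV (columns term, category, source)."""
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        return _parse_lexicon_rows(csv.DictReader(fh), str(path))


def _parse_lexicon_rows(reader, source_name: str) -> Lexicon:
    if reader.fieldnames is None:
        raise EmptyLexiconError(f"{source_name}: empty lexicon file")
    if not {"term", "category"} <= set(reader.fieldnames):
        raise SchemaError(
            f"{source_name}: lexicon CSV needs columns term, category (optional source)"
        )
    entries = []
    for row in reader:
        tokens = _normalize_term(row["term"])
        entries.append(
            LexiconEntry(
                term_tokens=tokens,
                category=Category.parse(row["category"]),
                source=(row.get("source") or "").strip(),
            )
        )
    if not entries:
        raise EmptyLexiconError(f"{source_name}: lexicon has zero entries")
    return Lexicon(entries)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon CSV; ``cname`` is spelled CNAME on disk, as in source files."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "category", "source"])
        for entry in lexicon:
            term = " ".join(
                "CNAME" if tok == "cname" else tok for tok in entry.term_tokens
            )
            writer.writerow([term, entry.category.value, entry.source])


def bundled_example_lexicon() -> Lexicon:
    """The small illustrative lexicon shipped with the package.

    It is a fixture for tests, documentation and the synthetic-corpus
    generator — not a validated clinical instrument. Category assignments for
    terms whose published category is not stated are fixture choices.
    """
    ref = resources.files("recovlex").joinpath("data/example_lexicon.csv")
    with resources.as_file(ref) as path:
        return load_lexicon(path)
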