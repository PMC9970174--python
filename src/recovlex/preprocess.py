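"""Tokenisation and sentence normalisation.

Documents are segmented at terminal punctuation and hard line breaks, then
normalised toward a consistent sentence length: sentences longer than 30
words are split into strings of at most 20 words, cutting at internal
punctuation where possible, and sentences shorter than 5 words are merged
into adjacent sentences. Punctuation marks are kept as flagged tokens but
never counted as words.

The split-then-merge order is fixed; merged output is not re-split, so a
merge can in principle exceed the 30-word ceiling. Short sentences merge
forward into the following sentence, and backward only when they are last
in the document.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .corpus_model import RawDocument
from .errors import EmptyDocumentError, EmptySentenceError

__all__ = [
    "SegmentationConfig",
    "Sentence",
    "NormalizedDocument",
    "NormalizedCorpus",
    "tokenize",
    "is_word_token",
    "word_count",
    "segment_sentences",
    "split_long_sentence",
    "merge_short_sentences",
    "normalize_document",
    "normalize_corpus",
]

logger = logging.getLogger(__name__)

# Word: alphanumeric runs, with internal hyphens/apostrophes kept inside the
# token (so "well-being" is one matchable unigram). Anything else non-space
# becomes a standalone punctuation token.
_TOKEN_RE = re.compile(r"[^\W_]+(?:['’\-][^\W_]+)*|[^\w\s]", re.UNICODE)

# Segments end at terminal punctuation runs; newlines are hard boundaries.
_SEGMENT_RE = re.compile(r"[^.!?\n]*[.!?]+|[^.!?\n]+")


@dataclass(frozen=True)
class SegmentationConfig:
    """Sentence-length normalisation thresholds, in word tokens."""

    max_sentence_tokens: int = 30
    chunk_max_tokens: int = 20
    min_sentence_tokens: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.min_sentence_tokens <= self.chunk_max_tokens <= self.max_sentence_tokens):
            raise ValueError(
                "require 0 < min_sentence_tokens <= chunk_max_tokens <= max_sentence_tokens"
            )


@dataclass(frozen=True)
class Sentence:
    """A normalised sentence: ordered lowercase tokens, indexed within its document."""

    doc_id: str
    index: int
    tokens: tuple[str, ...]

    @property
    def word_tokens(self) -> tuple[str, ...]:
        return tuple(t for t in self.tokens if is_word_token(t))

    @property
    def n_words(self) -> int:
        return sum(1 for t in self.tokens if is_word_token(t))

    def text(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class NormalizedDocument:
    doc: RawDocument
    sentences: tuple[Sentence, ...]

    @property
    def doc_id(self) -> str:
        return self.doc.doc_id


@dataclass(frozen=True)
class NormalizedCorpus:
    documents: tuple[NormalizedDocument, ...]

    def __iter__(self):
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)


def is_word_token(token: str) -> bool:
    """A token counts as a word iff it contains at least one alphanumeric character."""
    return any(ch.isalnum() for ch in token)


def word_count(tokens) -> int:
    return sum(1 for t in tokens if is_word_token(t))


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens plus standalone punctuation tokens.

    Internal hyphens and apostrophes stay inside word tokens; the CNAME
    placeholder (any case) becomes the single token ``cname``.
    """
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


def segment_sentences(text: str) -> list[list[str]]:
    """Initial segmentation at terminal punctuation (. ! ?) and line breaks.

    Each unit is tokenised; units with no word tokens are dropped.
    """
    sentences = []
    for m in _SEGMENT_RE.finditer(text):
        tokens = tokenize(m.group(0))
        if word_count(tokens) > 0:
            sentences.append(tokens)
    return sentences


def split_long_sentence(tokens, cfg: SegmentationConfig = SegmentationConfig()) -> list[list[str]]:
    """Split a sentence longer than the 30-word ceiling into <=20-word strings.

    Each cut is placed at the internal punctuation mark nearest to (and not
    beyond) 20 words from the chunk start — ties toward the later mark — or
    at exactly 20 words when no punctuation lies in that window. The
    concatenation of the chunks always equals the input.
    """
    tokens = list(tokens)
    if not tokens:
        raise EmptySentenceError("cannot split an empty sentence")
    if word_count(tokens) <= cfg.max_sentence_tokens:
        return [tokens]
    chunks: list[list[str]] = []
    rest = tokens
    while word_count(rest) > cfg.chunk_max_tokens:
        cut = _find_cut(rest, cfg.chunk_max_tokens)
        chunks.append(rest[:cut])
        rest = rest[cut:]
    chunks.append(rest)
    return chunks


def _find_cut(tokens: list[str], chunk_max: int) -> int:
    """Index to cut before, for a chunk of at most ``chunk_max`` words."""
    best = None  # (words_before, index) of best punctuation cut
    words = 0
    last_word_idx = None
    for i, tok in enumerate(tokens):
        if is_word_token(tok):
            words += 1
            if words > chunk_max:
                break
            last_word_idx = i
        else:
            # internal punctuation: needs >=1 word before and >=1 word after
            if 0 < words <= chunk_max and word_count(tokens[i + 1 :]) > 0:
                if best is None or words >= best[0]:
                    best = (words, i)
    if best is not None:
        return best[1] + 1
    # no usable punctuation in the window: cut right after the chunk_max-th word
    assert last_word_idx is not None
    return last_word_idx + 1


def merge_short_sentences(sentences, cfg: SegmentationConfig = SegmentationConfig()) -> list[list[str]]:
    """Merge sentences shorter than the 5-word floor into adjacent sentences.

    Scanning left to right, a short sentence is joined with the following one
    (token order preserved); a short *final* sentence joins backward. The scan
    repeats until nothing mergeable remains or a single sentence is left.
    """
    out = [list(s) for s in sentences]
    i = 0
    while len(out) > 1 and i < len(out):
        if word_count(out[i]) < cfg.min_sentence_tokens:
            if i + 1 < len(out):
                out[i : i + 2] = [out[i] + out[i + 1]]
            else:
                out[i - 1 : i + 1] = [out[i - 1] + out[i]]
                i -= 1
            # re-examine the merged sentence in place
        else:
            i += 1
    return out


def normalize_document(
    doc: RawDocument, cfg: SegmentationConfig = SegmentationConfig()
) -> list[Sentence]:
    """Full sentence normalisation of one document.

    Segment, split long sentences, then merge short ones over the flattened
    result; word counts never include punctuation tokens.
    """
    units = segment_sentences(doc.text)
    if not units:
        raise EmptyDocumentError(f"document {doc.doc_id!r} has no word tokens")
    split_units: list[list[str]] = []
    for unit in units:
        split_units.extend(split_long_sentence(unit, cfg))
    merged = merge_short_sentences(split_units, cfg)
    if len(merged) == 1 and word_count(merged[0]) < cfg.min_sentence_tokens:
        logger.warning(
            "document %s has only %d word tokens (below the %d-word floor); kept as one sentence",
            doc.doc_id,
            word_count(merged[0]),
            cfg.min_sentence_tokens,
        )
    return [
        Sentence(doc_id=doc.doc_id, index=i, tokens=tuple(toks))
        for i, toks in enumerate(merged)
    ]


def normalize_corpus(corpus, cfg: SegmentationConfig = SegmentationConfig()) -> NormalizedCorpus:
    docs = tuple(
        NormalizedDocument(doc=d, sentences=tuple(normalize_document(d, cfg)))
        for d in corpus
    )
    return NormalizedCorpus(documents=docs)
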