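"""Sentence-level matching of lexicon terms and category labelling.

Presence of a language category in a sentence is boolean and multi-label: a
sentence carries a category if at least one of that category's terms occurs
in it, and carries it only once however many terms matched — the unit of
measurement is the sentence, which avoids double counting instances spanning
several dictionary terms.

By default matching runs over the sentence's *word* tokens, so incidental
punctuation between words does not break an ngram ("cname, will" still
matches the bigram "cname will"). The conservative alternative, where
punctuation blocks adjacency, is available via ``punctuation_blocks=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .corpus_model import Arm
from .errors import EmptySentenceError
from .lexicon import MAX_TERM_TOKENS, Category, Lexicon
from .preprocess import NormalizedCorpus, is_word_token

__all__ = ["SentenceTags", "TaggedDocument", "TaggedCorpus", "match_sentence", "tag_corpus"]


@dataclass(frozen=True)
class SentenceTags:
    """Matched terms and the induced category set for one sentence."""

    doc_id: str
    index: int
    matched_terms: frozenset[str]
    categories: frozenset[Category]


@dataclass(frozen=True)
class TaggedDocument:
    doc_id: str
    arm: Arm
    tags: tuple[SentenceTags, ...]

    @property
    def n_sentences(self) -> int:
        return len(self.tags)


@dataclass(frozen=True)
class TaggedCorpus:
    """Per-sentence tags for a normalised corpus under one lexicon."""

    corpus: NormalizedCorpus
    documents: tuple[TaggedDocument, ...]

    def __iter__(self) -> Iterable[TaggedDocument]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def n_sentences(self) -> int:
        return sum(d.n_sentences for d in self.documents)

    def all_tags(self) -> list[SentenceTags]:
        return [t for d in self.documents for t in d.tags]


def _sentence_ngrams(words: tuple[str, ...] | list[str], max_n: int) -> set[tuple[str, ...]]:
    grams: set[tuple[str, ...]] = set()
    L = len(words)
    for n in range(1, min(max_n, L) + 1):
        for i in range(L - n + 1):
            grams.add(tuple(words[i : i + n]))
    return grams


def match_sentence(
    tokens, lexicon: Lexicon, punctuation_blocks: bool = False
) -> frozenset[str]:
    """Distinct lexicon terms occurring contiguously in a sentence.

    Overlapping matches all count; repeated occurrences of a term count once.
    Raises :class:`EmptySentenceError` on an empty token list.
    """
    tokens = list(tokens)
    if not tokens:
        raise EmptySentenceError("cannot match an empty sentence")
    if punctuation_blocks:
        words = tokens
    else:
        words = [t for t in tokens if is_word_token(t)]
    grams = _sentence_ngrams(words, MAX_TERM_TOKENS)
    by_tokens = lexicon.by_tokens
    return frozenset(
        " ".join(g) for g in grams.intersection(by_tokens)
    )


def tag_corpus(
    corpus: NormalizedCorpus, lexicon: Lexicon, punctuation_blocks: bool = False
) -> TaggedCorpus:
    """Tag every sentence of a normalised corpus; deterministic given inputs."""
    by_tokens = lexicon.by_tokens
    docs = []
    for ndoc in corpus:
        tags = []
        for sent in ndoc.sentences:
            if not sent.tokens:
                raise EmptySentenceError(
                    f"document {ndoc.doc_id!r}, sentence {sent.index}: empty"
                )
            words = sent.tokens if punctuation_blocks else sent.word_tokens
            grams = _sentence_ngrams(words, MAX_TERM_TOKENS)
            matched = grams.intersection(by_tokens)
            tags.append(
                SentenceTags(
                    doc_id=ndoc.doc_id,
                    index=sent.index,
                    matched_terms=frozenset(" ".join(g) for g in matched),
                    categories=frozenset(by_tokens[g].category for g in matched),
                )
            )
        docs.append(TaggedDocument(doc_id=ndoc.doc_id, arm=ndoc.doc.arm, tags=tuple(tags)))
    return TaggedCorpus(corpus=corpus, documents=tuple(docs))
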