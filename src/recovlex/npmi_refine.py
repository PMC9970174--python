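"""Normalised pointwise mutual information for dictionary refinement.

NPMI compares how often a term and a category label co-occur at sentence
level with how often they would co-occur if independent:

    npmi = ln(p_xy / (p_x * p_y)) / (-ln p_xy)

with p_x = n_item/N, p_y = n_cat/N, p_xy = n_joint/N over N sentences. The
value lies in [-1, 1] and reads like a correlation coefficient: 1 at perfect
co-occurrence (n_joint = n_item = n_cat), 0 at exact independence, and -1 by
convention when the pair never co-occurs (the mathematical limit; no
smoothing is applied, so small fixture corpora are not distorted).

Refinement is advisory only: weak or misaligned dictionary terms are flagged
for human review, and strongly associated unlisted ngrams are exported as
candidates — inclusion remains a human decision.

A dictionary term scored against its *own* category would trivially reach
npmi near 1, since the term itself induces the label. Own-category scores are
therefore computed leave-one-term-out (LOTO): category labels are recomputed
with the term removed from the lexicon before counting. The naive mode is
available via ``leave_one_out=False`` for comparability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import SparseTermError, UndefinedAssociationError
from .lexicon import MAX_TERM_TOKENS, Category, Lexicon
from .tagger import TaggedCorpus, _sentence_ngrams

__all__ = [
    "NpmiScore",
    "RefineConfig",
    "Candidate",
    "WeakTermFlag",
    "RefinementReport",
    "npmi_from_counts",
    "term_category_association",
    "discover_candidates",
    "flag_weak_terms",
]


@dataclass(frozen=True)
class NpmiScore:
    """Sentence-level association between an item (term/ngram) and a category."""

    item: str
    category: Category
    n_item: int
    n_cat: int
    n_joint: int
    n_total: int
    npmi: float


@dataclass(frozen=True)
class RefineConfig:
    """Thresholds steering dictionary refinement.

    ``min_count`` is the occurrence floor below which association estimates
    are considered unstable; ``weak_threshold`` flags dictionary terms whose
    own-category NPMI falls below it; ``strong_threshold`` promotes
    unclassified ngrams to review candidates. All three are configuration
    defaults, not published constants.
    """

    min_count: int = 5
    weak_threshold: float = 0.2
    strong_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not -1 <= self.weak_threshold <= self.strong_threshold <= 1:
            raise ValueError("require -1 <= weak_threshold <= strong_threshold <= 1")


@dataclass(frozen=True)
class Candidate:
    """An unlisted ngram strongly associated with a category, for human review."""

    item: str
    category: Category
    npmi: float
    n_item: int
    n_joint: int
    examples: tuple[str, ...] = ()


@dataclass(frozen=True)
class WeakTermFlag:
    """A dictionary term whose association pattern warrants category review."""

    term: str
    category: Category
    own_npmi: float
    best_other_category: Category | None
    best_other_npmi: float | None
    reason: str


@dataclass(frozen=True)
class RefinementReport:
    flagged: tuple[WeakTermFlag, ...]
    skipped: tuple[tuple[str, str], ...] = field(default_factory=tuple)  # (term, reason)


def npmi_from_counts(n_joint: int, n_item: int, n_cat: int, n_total: int) -> float:
    """NPMI from sentence counts, natural log, zero-co-occurrence convention -1."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_item < 1 or n_cat < 1:
        raise UndefinedAssociationError(
            f"association undefined for n_item={n_item}, n_cat={n_cat}"
        )
    if not 0 <= n_joint <= min(n_item, n_cat) or max(n_item, n_cat) > n_total:
        raise ValueError(
            f"inconsistent counts n_joint={n_joint}, n_item={n_item}, "
            f"n_cat={n_cat}, n_total={n_total}"
        )
    if n_joint == 0:
        return -1.0
    if n_joint == n_item == n_cat:
        # perfect co-occurrence: ln(N/n)/ln(N/n) = 1 exactly (and the
        # n_joint = N limit, where the -ln(1) denominator vanishes)
        return 1.0
    p_xy = n_joint / n_total
    p_x = n_item / n_total
    p_y = n_cat / n_total
    return math.log(p_xy / (p_x * p_y)) / (-math.log(p_xy))


def term_category_association(
    tagged: TaggedCorpus,
    lexicon: Lexicon,
    term: str,
    cfg: RefineConfig = RefineConfig(),
    leave_one_out: bool = True,
) -> dict[Category, NpmiScore]:
    """NPMI of one dictionary term against every category.

    The own-category score is leave-one-term-out by default. Raises
    :class:`SparseTermError` below the occurrence floor and
    :class:`UndefinedAssociationError` when no labelled sentence remains for
    the own category after leave-one-out.
    """
    entry = lexicon.lookup(term)
    if entry is None:
        raise KeyError(f"term {term!r} is not in the lexicon")
    term_str = entry.term
    all_tags = [t for d in tagged for t in d.tags]
    n_total = len(all_tags)
    item_mask = [term_str in t.matched_terms for t in all_tags]
    n_item = sum(item_mask)
    if n_item < cfg.min_count:
        raise SparseTermError(
            f"term {term_str!r} occurs in {n_item} sentence(s); "
            f"floor is {cfg.min_count}"
        )
    scores: dict[Category, NpmiScore] = {}
    for cat in Category:
        if leave_one_out and cat == entry.category:
            cat_mask = [
                any(
                    mt != term_str and lexicon.category_of(mt) == cat
                    for mt in t.matched_terms
                )
                for t in all_tags
            ]
        else:
            cat_mask = [cat in t.categories for t in all_tags]
        n_cat = sum(cat_mask)
        if n_cat == 0:
            if cat == entry.category:
                raise UndefinedAssociationError(
                    f"no {cat.value!r} sentences remain for {term_str!r} "
                    "after leave-one-term-out"
                )
            continue  # category absent from the corpus: no score to report
        n_joint = sum(1 for i, c in zip(item_mask, cat_mask) if i and c)
        npmi = npmi_from_counts(n_joint, n_item, n_cat, n_total)
        scores[cat] = NpmiScore(
            item=term_str,
            category=cat,
            n_item=n_item,
            n_cat=n_cat,
            n_joint=n_joint,
            n_total=n_total,
            npmi=npmi,
        )
    return scores


def _contains_subsequence(hay: Sequence[str], needle: Sequence[str]) -> bool:
    n = len(needle)
    return any(tuple(hay[i : i + n]) == tuple(needle) for i in range(len(hay) - n + 1))


def discover_candidates(
    tagged: TaggedCorpus,
    lexicon: Lexicon,
    cfg: RefineConfig = RefineConfig(),
    max_examples: int = 3,
) -> list[Candidate]:
    """Unlisted 1-3 token ngrams strongly associated with a category.

    An ngram is excluded as a candidate for a category when it already
    contains one of that category's terms as a contiguous sub-sequence (it
    would only restate an existing entry). Results are sorted by NPMI then
    occurrence count (both descending), then lexicographically, and each
    candidate carries up to ``max_examples`` example sentences for review.
    """
    sentences = []  # (word_tokens, categories, text)
    for ndoc, tdoc in zip(tagged.corpus, tagged.documents):
        for sent, tags in zip(ndoc.sentences, tdoc.tags):
            sentences.append((sent.word_tokens, tags.categories, sent.text()))
    n_total = len(sentences)
    if n_total == 0:
        return []
    occ: dict[tuple[str, ...], list[int]] = {}
    for idx, (words, _, _) in enumerate(sentences):
        for gram in _sentence_ngrams(words, MAX_TERM_TOKENS):
            occ.setdefault(gram, []).append(idx)
    cat_counts = {c: sum(1 for _, cats, _ in sentences if c in cats) for c in Category}
    lex_terms = lexicon.by_tokens
    results: list[Candidate] = []
    for gram, idxs in occ.items():
        if len(idxs) < cfg.min_count or gram in lex_terms:
            continue
        for cat in Category:
            if cat_counts[cat] == 0:
                continue
            if any(
                e.category == cat and _contains_subsequence(gram, e.term_tokens)
                for e in lexicon
            ):
                continue
            joint_idxs = [i for i in idxs if cat in sentences[i][1]]
            npmi = npmi_from_counts(len(joint_idxs), len(idxs), cat_counts[cat], n_total)
            if npmi >= cfg.strong_threshold:
                results.append(
                    Candidate(
                        item=" ".join(gram),
                        category=cat,
                        npmi=npmi,
                        n_item=len(idxs),
                        n_joint=len(joint_idxs),
                        examples=tuple(
                            sentences[i][2] for i in joint_idxs[:max_examples]
                        ),
                    )
                )
    results.sort(key=lambda c: (-c.npmi, -c.n_item, c.item, c.category.value))
    return results


def flag_weak_terms(
    tagged: TaggedCorpus,
    lexicon: Lexicon,
    cfg: RefineConfig = RefineConfig(),
    leave_one_out: bool = True,
) -> RefinementReport:
    """Dictionary terms whose classification should be reviewed.

    A term is flagged when its (leave-one-out) own-category NPMI falls below
    ``weak_threshold``, or when some other category associates more strongly.
    Terms too sparse to score — or with no labelled own-category sentences
    left after leave-one-out — are reported separately, not flagged.
    """
    flagged: list[WeakTermFlag] = []
    skipped: list[tuple[str, str]] = []
    for entry in lexicon:
        try:
            scores = term_category_association(
                tagged, lexicon, entry.term, cfg, leave_one_out=leave_one_out
            )
        except SparseTermError:
            skipped.append((entry.term, "sparse"))
            continue
        except UndefinedAssociationError:
            skipped.append((entry.term, "own-category undefined after leave-one-out"))
            continue
        own = scores[entry.category]
        others = [s for c, s in scores.items() if c != entry.category]
        best_other = max(others, key=lambda s: s.npmi) if others else None
        reasons = []
        if own.npmi < cfg.weak_threshold:
            reasons.append(f"own-category npmi {own.npmi:.3f} < {cfg.weak_threshold}")
        if best_other is not None and best_other.npmi > own.npmi:
            reasons.append(
                f"stronger association with {best_other.category.value} "
                f"({best_other.npmi:.3f} > {own.npmi:.3f})"
            )
        if reasons:
            flagged.append(
                WeakTermFlag(
                    term=entry.term,
                    category=entry.category,
                    own_npmi=own.npmi,
                    best_other_category=best_other.category if best_other else None,
                    best_other_npmi=best_other.npmi if best_other else None,
                    reason="; ".join(reasons),
                )
            )
    return RefinementReport(flagged=tuple(flagged), skipped=tuple(skipped))
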