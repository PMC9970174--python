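"""Synthetic pre/post corpora with known planted category rates.

The generator emulates the statistical structure the analysis assumes: two
document cohorts (defaults 50 pre, 77 post), roughly 53 sentences per
document averaging 16 words, and each sentence independently carrying each
language category with a per-arm Bernoulli rate. Planting a category inserts
one of that category's lexicon terms (sampled by weight) into neutral filler
text; multi-term sentences arise only through multiple categories. Default
rates (REHAB 0.37 pre / 0.48 post, PERSON 0.22 / 0.22, PEJ 0.023 / 0.02)
mirror the reported study prevalences so the end-to-end synthetic study
reproduces the headline contrast in expectation.

The default filler vocabulary is disjoint from the bundled lexicon's tokens,
so dictionary matches in generated text come only from planted terms. The
generator makes no attempt at clinically plausible prose.

Sentence word counts are drawn around the configured mean inside the [5, 30]
band, so the normalisation stage neither splits nor merges generated
sentences and ground-truth sentence indices line up with normalised ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_model import Arm, Corpus, RawDocument, write_table
from .errors import SpecError
from .lexicon import Category, Lexicon, bundled_example_lexicon

__all__ = [
    "SynthSpec",
    "PlantedSentence",
    "GroundTruth",
    "generate_corpus",
    "write_ground_truth",
    "idealized_fixture",
    "DEFAULT_FILLER_VOCAB",
]

# Neutral words; intentionally free of every token used by the bundled
# example lexicon (no copulas or ability/negation words).
DEFAULT_FILLER_VOCAB: tuple[str, ...] = (
    "the", "a", "an", "to", "of", "and", "for", "with", "at", "on", "over",
    "team", "weekly", "review", "session", "support", "goals", "community",
    "housing", "worker", "attended", "reported", "discussed", "continues",
    "activities", "group", "program", "staff", "during", "this", "month",
    "progress", "focus", "time", "home", "visit", "contact", "family",
    "medication", "appointment", "clinic", "morning", "service", "meeting",
    "week", "regular", "ongoing", "current", "local", "daily", "routine",
    "garden", "walking", "shopping", "budget", "travel", "skills", "engaged",
    "afternoon", "transport", "library", "volunteer", "course", "exercise",
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study; defaults reproduce the reported design."""

    n_docs_pre: int = 50
    n_docs_post: int = 77
    sentences_per_doc_mean: float = 53.0
    sentences_per_doc_dispersion: float | None = None  # None -> Poisson counts
    words_per_sentence_mean: float = 16.0
    min_words: int = 5
    max_words: int = 30
    category_rates_pre: Mapping[Category, float] = field(
        default_factory=lambda: {
            Category.REHAB: 0.37,
            Category.PERSON: 0.22,
            Category.PEJ: 0.023,
        }
    )
    category_rates_post: Mapping[Category, float] = field(
        default_factory=lambda: {
            Category.REHAB: 0.48,
            Category.PERSON: 0.22,
            Category.PEJ: 0.02,
        }
    )
    term_weights: Mapping[str, float] | None = None  # term -> weight; None = uniform
    filler_vocab: tuple[str, ...] = DEFAULT_FILLER_VOCAB
    companion_terms: Mapping[Category, Sequence[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs_pre < 1 or self.n_docs_post < 1:
            raise SpecError("document counts must be >= 1")
        if not self.filler_vocab:
            raise SpecError("filler vocabulary must be non-empty")
        for rates in (self.category_rates_pre, self.category_rates_post):
            for cat, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise SpecError(f"rate for {cat} out of [0,1]: {r}")


@dataclass(frozen=True)
class PlantedSentence:
    """Ground truth for one generated sentence."""

    doc_id: str
    index: int
    categories: frozenset[Category]
    terms: tuple[str, ...]


@dataclass(frozen=True)
class GroundTruth:
    """Planted categories/terms per sentence, with helpers for empirical rates."""

    sentences: tuple[PlantedSentence, ...]

    def planted_rate(self, doc_ids: set[str], category: Category) -> float:
        pool = [s for s in self.sentences if s.doc_id in doc_ids]
        if not pool:
            return float("nan")
        return sum(1 for s in pool if category in s.categories) / len(pool)


def _term_sampler(lexicon: Lexicon, spec: SynthSpec):
    """Per-category (terms, probabilities) for weighted term sampling."""
    samplers: dict[Category, tuple[list[tuple[str, ...]], np.ndarray]] = {}
    rates_union = {
        c: max(spec.category_rates_pre.get(c, 0.0), spec.category_rates_post.get(c, 0.0))
        for c in Category
    }
    for cat in Category:
        entries = lexicon.terms_of(cat)
        if spec.term_weights is None:
            weights = np.ones(len(entries))
        else:
            weights = np.array(
                [spec.term_weights.get(e.term, 1.0) for e in entries], dtype=float
            )
        if (weights < 0).any():
            raise SpecError("term weights must be non-negative")
        total = weights.sum()
        if rates_union[cat] > 0 and (not entries or total == 0):
            raise SpecError(
                f"category {cat.value!r} has positive rate but no weighted lexicon terms"
            )
        probs = weights / total if total > 0 else weights
        samplers[cat] = ([e.term_tokens for e in entries], probs)
    return samplers


def _emit_token(tok: str) -> str:
    return "CNAME" if tok == "cname" else tok


def generate_corpus(
    spec: SynthSpec = SynthSpec(), lexicon: Lexicon | None = None
) -> tuple[Corpus, Corpus, GroundTruth]:
    """Generate the pre and post corpora plus planted ground truth.

    Fully reproducible from ``spec.seed``: identical spec gives byte-identical
    corpora across runs and platforms.
    """
    if lexicon is None:
        lexicon = bundled_example_lexicon()
    rng = np.random.default_rng(spec.seed)
    samplers = _term_sampler(lexicon, spec)
    companions = {
        cat: [tuple(p.lower().split()) for p in phrases]
        for cat, phrases in (spec.companion_terms or {}).items()
    }
    truth: list[PlantedSentence] = []
    corpora: dict[Arm, list[RawDocument]] = {Arm.PRE: [], Arm.POST: []}
    arm_specs = [
        (Arm.PRE, spec.n_docs_pre, spec.category_rates_pre),
        (Arm.POST, spec.n_docs_post, spec.category_rates_post),
    ]
    cats = list(Category)
    filler = np.array(spec.filler_vocab)
    for arm, n_docs, rates in arm_specs:
        n_sents = _draw_counts(rng, spec, n_docs)
        rate_vec = np.array([rates.get(c, 0.0) for c in cats])
        for d in range(n_docs):
            doc_id = f"{arm.value}-{d + 1:03d}"
            ns = int(n_sents[d])
            planted = rng.random((ns, len(cats))) < rate_vec
            lengths = np.clip(
                rng.poisson(spec.words_per_sentence_mean, size=ns),
                spec.min_words,
                spec.max_words,
            )
            sentences = []
            for s in range(ns):
                cats_here = [c for j, c in enumerate(cats) if planted[s, j]]
                term_units: list[tuple[str, ...]] = []
                terms_here: list[str] = []
                for c in cats_here:
                    terms, probs = samplers[c]
                    pick = terms[rng.choice(len(terms), p=probs)]
                    term_units.append(pick)
                    terms_here.append(" ".join(pick))
                    for phrase in companions.get(c, []):
                        term_units.append(phrase)
                n_term_words = sum(len(u) for u in term_units)
                n_filler = int(lengths[s]) - n_term_words
                n_filler = max(n_filler, spec.min_words - n_term_words, 0)
                n_filler = min(n_filler, max(spec.max_words - n_term_words, 0))
                units: list[tuple[str, ...]] = list(term_units)
                if n_filler:
                    units += [(w,) for w in rng.choice(filler, size=n_filler)]
                order = rng.permutation(len(units))
                tokens = [tok for k in order for tok in units[k]]
                sentences.append(" ".join(_emit_token(t) for t in tokens) + ".")
                truth.append(
                    PlantedSentence(
                        doc_id=doc_id,
                        index=s,
                        categories=frozenset(cats_here),
                        terms=tuple(terms_here),
                    )
                )
            corpora[arm].append(
                RawDocument(doc_id=doc_id, arm=arm, text=" ".join(sentences))
            )
    return (
        Corpus(corpora[Arm.PRE]),
        Corpus(corpora[Arm.POST]),
        GroundTruth(sentences=tuple(truth)),
    )


def _draw_counts(rng: np.random.Generator, spec: SynthSpec, n_docs: int) -> np.ndarray:
    """Per-document sentence counts: Poisson, or gamma-Poisson when overdispersed."""
    mean = spec.sentences_per_doc_mean
    k = spec.sentences_per_doc_dispersion
    if k is None:
        counts = rng.poisson(mean, size=n_docs)
    else:
        # negative binomial via gamma-Poisson: variance = mean + mean^2/k
        lam = rng.gamma(shape=k, scale=mean / k, size=n_docs)
        counts = rng.poisson(lam)
    return np.maximum(counts, 1)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = [
        {
            "doc_id": s.doc_id,
            "sentence_index": s.index,
            "categories": ";".join(sorted(c.value for c in s.categories)),
            "terms": ";".join(s.terms),
        }
        for s in truth.sentences
    ]
    write_table(rows, path, key=None, columns=["doc_id", "sentence_index", "categories", "terms"])


# --------------------------------------------------------------------------
# Hand-checked worked fixture


def idealized_fixture() -> tuple[Corpus, Corpus, dict]:
    """A tiny worked corpus with hand-verified expectations.

    Twelve sentences across one pre and one post document, every sentence
    already inside the 5-30 word band (so normalisation is the identity), and
    a companion ``expectations`` dict holding hand-computed tags, document
    scores, and NPMI counts for the bigram "cname will". Used as the
    cross-module regression anchor.
    """
    pre = Corpus([
        RawDocument(
            doc_id="fix-pre-1",
            arm=Arm.PRE,
            text=(
                "CNAME will attend the community garden group this week. "
                "The team visited CNAME at home during the morning. "
                "CNAME was upset about the housing delay last month. "
                "Metabolic monitoring continues at the local clinic every fortnight. "
                "CNAME has an enduring interest in photography and music. "
                "Staff noted CNAME remains non-compliant with the medication plan."
            ),
        )
    ])
    post = Corpus([
        RawDocument(
            doc_id="fix-post-1",
            arm=Arm.POST,
            text=(
                "CNAME will focus on well-being goals over the coming weeks. "
                "The plan supports independence in daily shopping and travel. "
                "CNAME reported feeling hopeful about the return to study. "
                "Metabolic monitoring continues with support from the general practice. "
                "CNAME was tired after the group session on Tuesday. "
                "The chronic staffing shortage delayed two review meetings this quarter."
            ),
        )
    ])
    expectations = {
        # per sentence: set of matched terms and set of categories
        "tags": {
            ("fix-pre-1", 0): ({"cname will"}, {Category.REHAB}),
            ("fix-pre-1", 1): (set(), set()),
            ("fix-pre-1", 2): ({"cname was"}, {Category.PERSON}),
            ("fix-pre-1", 3): ({"metabolic monitoring"}, {Category.REHAB}),
            ("fix-pre-1", 4): ({"enduring"}, {Category.PERSON}),
            ("fix-pre-1", 5): ({"non-compliant"}, {Category.PEJ}),
            ("fix-post-1", 0): ({"cname will", "well-being"}, {Category.REHAB}),
            ("fix-post-1", 1): ({"independence"}, {Category.REHAB}),
            ("fix-post-1", 2): (set(), set()),
            ("fix-post-1", 3): ({"metabolic monitoring"}, {Category.REHAB}),
            ("fix-post-1", 4): ({"cname was"}, {Category.PERSON}),
            ("fix-post-1", 5): ({"chronic"}, {Category.PEJ}),
        },
        # percent of the 6 sentences per document carrying each category
        "category_pct": {
            "fix-pre-1": {
                Category.REHAB: 100 * 2 / 6,
                Category.PERSON: 100 * 2 / 6,
                Category.PEJ: 100 * 1 / 6,
            },
            "fix-post-1": {
                Category.REHAB: 100 * 3 / 6,
                Category.PERSON: 100 * 1 / 6,
                Category.PEJ: 100 * 1 / 6,
            },
        },
        # "cname will" over the pooled 12 sentences, own category (REHAB)
        # scored leave-one-term-out: remaining REHAB sentences are pre s3 and
        # post s0 (via well-being), s1, s3 -> n_cat 4; joint only post s0.
        "npmi_cname_will": {
            "n_total": 12,
            "n_item": 2,
            Category.REHAB: {"n_cat": 4, "n_joint": 1},
            Category.PERSON: {"n_cat": 3, "n_joint": 0, "npmi": -1.0},
        },
    }
    return pre, post, expectations
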