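"""Document-level prevalence metrics and pre/post cohort comparison.

The prevalence of a language category in a document is the percentage of its
sentences in which the category appears (0-100); the same metric applies to
individual terms. Cohorts are compared on the *unweighted mean of the
document-level percentages*, with Welch's unequal-variance t-test — chosen
because the two arms differ in size and no variance equality is assumed.

Relative change is 100*(post-pre)/pre on the unrounded cohort means; it is
undefined (and reported as absent) when the pre-intervention mean is zero.
The term-change table filters on raw p-values, and an unfiltered companion
with Benjamini-Hochberg adjusted p-values is always produced alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus_model import Arm
from .errors import (
    EmptyDocumentError,
    InsufficientDataError,
    UndefinedRelativeChangeError,
)
from .lexicon import Category
from .tagger import TaggedCorpus, TaggedDocument

__all__ = [
    "DocumentScore",
    "CohortComparison",
    "TermChangeTable",
    "score_document",
    "score_corpus",
    "welch_t_test",
    "relative_change",
    "compare_cohorts",
    "term_change_table",
]


@dataclass(frozen=True)
class DocumentScore:
    """Per-document prevalence: percent of sentences carrying each category/term."""

    doc_id: str
    arm: Arm
    n_sentences: int
    category_pct: Mapping[Category, float]
    term_pct: Mapping[str, float]


@dataclass(frozen=True)
class CohortComparison:
    """One pre/post contrast row for a category or an individual term."""

    item: str
    pre_mean_pct: float
    post_mean_pct: float
    abs_change_points: float
    relative_change_pct: float | None
    t_statistic: float
    welch_df: float
    p_value: float
    p_bh: float | None = None


@dataclass(frozen=True)
class TermChangeTable:
    """Term-level contrasts: the raw-p filtered table plus the full BH-adjusted one."""

    significant: tuple[CohortComparison, ...]
    all_terms: tuple[CohortComparison, ...]
    alpha: float


def score_document(tagged_doc: TaggedDocument) -> DocumentScore:
    """Percentage of sentences in which each category (and each term) appears."""
    n = tagged_doc.n_sentences
    if n == 0:
        raise EmptyDocumentError(f"document {tagged_doc.doc_id!r} has zero sentences")
    cat_counts = {c: 0 for c in Category}
    term_counts: dict[str, int] = {}
    for tags in tagged_doc.tags:
        for c in tags.categories:
            cat_counts[c] += 1
        for t in tags.matched_terms:
            term_counts[t] = term_counts.get(t, 0) + 1
    return DocumentScore(
        doc_id=tagged_doc.doc_id,
        arm=tagged_doc.arm,
        n_sentences=n,
        category_pct={c: 100.0 * k / n for c, k in cat_counts.items()},
        term_pct={t: 100.0 * k / n for t, k in term_counts.items()},
    )


def score_corpus(tagged: TaggedCorpus) -> list[DocumentScore]:
    return [score_document(d) for d in tagged]


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's two-sample t statistic, Welch-Satterthwaite df, two-sided p.

    Degenerate convention: zero variance in both groups with equal means gives
    (t=0, df=n_a+n_b-2, p=1); with unequal means the difference is certain
    under the model and p=0 with an infinite t of the appropriate sign.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"Welch t-test needs >=2 observations per group (got {len(a)}, {len(b)})"
        )
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InsufficientDataError("non-finite values passed to welch_t_test")
    df_pooled = float(len(a) + len(b) - 2)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, df_pooled, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), df_pooled, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def relative_change(pre_mean: float, post_mean: float) -> float:
    """Relative change in percent of the pre-intervention mean."""
    if pre_mean == 0:
        raise UndefinedRelativeChangeError(
            "relative change undefined for a zero pre-intervention mean; "
            "report the absolute change instead"
        )
    return 100.0 * (post_mean - pre_mean) / pre_mean


def _comparison_row(
    item: str, pre_values: np.ndarray, post_values: np.ndarray
) -> CohortComparison:
    pre_mean = float(np.mean(pre_values))
    post_mean = float(np.mean(post_values))
    t, df, p = welch_t_test(pre_values, post_values)
    try:
        rel = relative_change(pre_mean, post_mean)
    except UndefinedRelativeChangeError:
        rel = None
    return CohortComparison(
        item=item,
        pre_mean_pct=pre_mean,
        post_mean_pct=post_mean,
        abs_change_points=post_mean - pre_mean,
        relative_change_pct=rel,
        t_statistic=t,
        welch_df=df,
        p_value=p,
    )


def _check_cohorts(tagged_pre: TaggedCorpus, tagged_post: TaggedCorpus) -> None:
    for name, cohort in (("pre", tagged_pre), ("post", tagged_post)):
        if len(cohort) < 2:
            raise InsufficientDataError(
                f"{name} cohort has {len(cohort)} document(s); need >=2 for a t-test"
            )


def compare_cohorts(
    tagged_pre: TaggedCorpus, tagged_post: TaggedCorpus
) -> list[CohortComparison]:
    """Category-level pre/post contrast (one row per language category)."""
    _check_cohorts(tagged_pre, tagged_post)
    pre_scores = score_corpus(tagged_pre)
    post_scores = score_corpus(tagged_post)
    rows = []
    for cat in Category:
        pre_vals = np.array([s.category_pct[cat] for s in pre_scores])
        post_vals = np.array([s.category_pct[cat] for s in post_scores])
        rows.append(_comparison_row(cat.value, pre_vals, post_vals))
    return rows


def term_change_table(
    tagged_pre: TaggedCorpus, tagged_post: TaggedCorpus, alpha: float = 0.05
) -> TermChangeTable:
    """Per-term pre/post contrast over every term seen in either cohort.

    Documents where a term never occurs contribute 0% for that term. The
    ``significant`` view keeps rows with raw p < alpha, sorted by the absolute
    change in percentage points (descending); ``all_terms`` carries every row
    with a BH-adjusted p-value.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    _check_cohorts(tagged_pre, tagged_post)
    pre_scores = score_corpus(tagged_pre)
    post_scores = score_corpus(tagged_post)
    terms = sorted(
        {t for s in pre_scores + post_scores for t in s.term_pct}
    )
    rows = []
    for term in terms:
        pre_vals = np.array([s.term_pct.get(term, 0.0) for s in pre_scores])
        post_vals = np.array([s.term_pct.get(term, 0.0) for s in post_scores])
        rows.append(_comparison_row(term, pre_vals, post_vals))
    if rows:
        p_bh = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        rows = [replace(r, p_bh=float(q)) for r, q in zip(rows, p_bh)]
    significant = tuple(
        sorted(
            (r for r in rows if r.p_value < alpha),
            key=lambda r: (-abs(r.abs_change_points), r.item),
        )
    )
    return TermChangeTable(
        significant=significant, all_terms=tuple(rows), alpha=alpha
    )
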