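# Methods

This note documents the measurement model implemented by `recovlex`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Measurement model

The unit of analysis is the *sentence*; the unit of reporting is the
*document*. A sentence carries a language category when at least one of that
category's lexicon terms occurs in it as a contiguous sequence of word
tokens. Coding is boolean and multi-label: a sentence may carry several
categories, but carries each at most once however many of its terms match.
This deliberately avoids double counting a single language instance that
happens to contain two or more dictionary terms, at the cost of insensitivity
to within-sentence intensity.

A document's score for a category (or term) is the percentage of its
sentences carrying it. Cohorts are summarised by the unweighted mean of
document-level percentages — every document counts equally, regardless of
length — rather than by a pooled sentence-level proportion. The two
summaries differ when document length correlates with language use; the
document-level mean is the one reported because the document is the clinical
and administrative unit of the audit.

### Sentence normalisation

Raw text is segmented at terminal punctuation (`.` `!` `?`) and hard line
breaks. To keep sentence length comparable across writing styles:

* sentences longer than `max_sentence_tokens` (default 30) words are split
  into chunks of at most `chunk_max_tokens` (default 20) words. Each cut is
  placed at the internal punctuation mark nearest to, and not beyond, the
  20-word limit — ties between equally placed marks resolve to the later one,
  which maximises chunk evenness under a single left-to-right pass — and at
  exactly 20 words when no punctuation lies in the window;
* sentences shorter than `min_sentence_tokens` (default 5) words are merged
  forward into the following sentence, a trailing short sentence backward
  into the preceding one, repeating until stable.

Split runs before merge, and merged output is not re-split, so a merge can in
principle exceed 30 words; this is accepted and documented rather than
iterated, keeping the procedure a terminating two-pass rule. Punctuation
marks are carried as flagged tokens but excluded from every word count.
Word tokens keep internal hyphens and apostrophes (so `well-being` is one
matchable unigram), and the de-identification placeholder `CNAME` (any case)
becomes the token `cname`, which may itself participate in dictionary
bigrams such as `cname will`.

A document whose total word count is below the 5-word floor is retained as a
single short sentence with a logged warning; normalisation of text already
inside the [5, 30] band is the identity (property-tested).

### Matching

Terms are literal ngrams of 1–3 lowercase tokens; no stemming, no gaps.
By default matching runs over the word-token sequence, so punctuation
between words does not break adjacency (`cname, will` still matches
`cname will`); the stricter behaviour is available with
`punctuation_blocks=True`. Term categories are disjoint — each term belongs
to exactly one category — while sentence coding is multi-label; conceptually
rehabilitation language is a subset of person-centred language, but the
PERSON list is operationalised as "person-centred terms that are not also
rehabilitation terms", which keeps the category counts separable.

### Inference

Arms are compared with Welch's unequal-variance t-test (two-sided,
Welch–Satterthwaite df). The unequal-variance form is used because the arms
differ in size and there is no evidence for equal variances. Degenerate
convention: zero variance in both groups with equal means reports t = 0,
p = 1.

Relative change is computed from unrounded means, so a contrast whose means
print as 37% and 48% reports a relative change near +29.7%, not the +28%/+30%
that rounding-before-dividing would give. When the pre-intervention mean is
zero, relative change is undefined and reported as absent (the absolute
change in percentage points is always reported).

The term-level table contains one row per term observed in either cohort,
with documents lacking the term contributing 0%. Because the table is
exploratory and its width grows with the lexicon, both a raw-p filtered view
(p < α, default α = 0.05, sorted by absolute change) and the full table with
Benjamini–Hochberg adjusted p-values are produced; the filter uses raw p to
keep the primary view comparable with conventional reporting, and the BH
column is there to be honest about multiplicity.

## NPMI refinement

Association between an item (a term or candidate ngram) and a category is
measured at sentence level by normalised pointwise mutual information with
natural logarithms:

    npmi = ln(p_xy / (p_x p_y)) / (-ln p_xy),  p_* = counts / N sentences.

Conventions and facts relied on (all enforced by tests):

* `npmi = -1` exactly when the pair never co-occurs (the mathematical limit;
  no add-one smoothing, which would visibly distort small corpora);
* `npmi = 1` exactly iff `n_joint = n_item = n_cat > 0` (returned as an exact
  1.0 rather than through floating-point evaluation, which rounds to 1 − ε);
* npmi is non-decreasing in `n_joint` and strictly increasing except in the
  degenerate family `n_item = n_cat = N`, where it is constant at −1 below
  perfect co-occurrence (both marginals saturate the corpus, so the
  normalised statistic carries no gradient there);
* npmi is symmetric in the two marginals.

A dictionary term scored naively against its own category reaches npmi ≈ 1
by construction, since the term itself induces the label. Own-category
scores are therefore **leave-one-term-out**: category labels are recomputed
with the term removed from the lexicon before counting. A term whose
category has no other term left has an undefined own-category association
and is reported as unscorable rather than flagged. The naive mode remains
available (`leave_one_out=False`) for comparison with tools that do not
correct for self-association.

Refinement outputs are advisory review queues, not automatic edits:

* **weak terms** — own-category npmi below `weak_threshold` (default 0.2) or
  a stronger association with a different category;
* **candidates** — unlisted 1–3 token ngrams with npmi ≥ `strong_threshold`
  (default 0.5) for some category, occurring in at least `min_count`
  (default 5) sentences, excluding ngrams that already contain one of that
  category's terms, each with up to three example sentences.

The three thresholds are configuration defaults chosen to be conservative on
corpora of a few thousand sentences; they are not published constants. Note
that sub-ngrams of a planted phrase tie with it at the same npmi; ties rank
by occurrence count and then lexicographically, so human review of the
candidate queue remains essential.

## Synthetic corpus generator

`SynthSpec` defaults describe the study conditions the pipeline is designed
for: 50 pre- and 77 post-intervention documents, Poisson sentence counts
with mean 53 per document (≈ 6,700 sentences in total), word counts
Poisson(16) clipped to [5, 30], and independent per-sentence Bernoulli
planting with rates REHAB 0.37/0.48, PERSON 0.22/0.22, PEJ 0.023/0.02
(pre/post). Planting a category inserts one term of that category — sampled
by configurable weights — at a random position in neutral filler text; the
default filler vocabulary is disjoint from every bundled lexicon token, so
tagged rates converge to planted rates and the generator/tagger pair is
internally consistent (verified within 3 binomial standard errors at 10⁴
sentences). An optional `companion_terms` map inserts unlisted phrases into
sentences planted with a given category, which is how candidate discovery is
exercised with known ground truth. Everything derives from a single
`numpy` generator seed; identical specs give byte-identical corpora.

What the generator does **not** emulate: clinically plausible prose, author
(case-manager) clustering, within-document correlation of categories,
temporal drift, or lexicon false positives from natural filler text
(real corpora will have all of these, plus terms matching in negated or
quoted contexts). Passing synthetic tests therefore demonstrates the
pipeline's statistical and mechanical correctness under the planted model,
not the clinical validity of any particular lexicon.

The per-document sentence-count dispersion of real corpora is unknown (only
a corpus mean is available); the generator defaults to Poisson counts and
exposes a gamma-Poisson (negative-binomial) dispersion parameter for
sensitivity analyses.

A 12-sentence hand-checked fixture (`idealized_fixture`) carries worked
expectations — tags, document scores and NPMI counts — and anchors the
cross-module regression tests.

## Calibration and problem sizes used in tests

The test suite replicates the synthetic study end to end across 100 seeds at
the full default specification and checks: REHAB means within 3 Monte-Carlo
standard errors of the planted 37/48, REHAB p < 0.001 in ≥ 95 seeds, and
PERSON/PEJ p > 0.05 in ≥ 85 seeds each (PEJ sits near the floor where small
planted differences are undetectable at these sample sizes, mirroring the
intended null). Type-I error of the Welch test at α = 0.05 is calibrated to
5% ± 2 pp over 1,000 replicates with identical planting; those replicates
draw document percentages directly from the generator's binomial
sentence-level model, which is exactly the distribution the text pipeline
induces when the filler vocabulary is disjoint from the lexicon. Unbiasedness
of cohort estimates is checked across 200 seeds on scaled-down corpora
(6 documents × 12 sentences) to keep the suite fast; the estimator is
invariant to that scaling.

## Bundled example lexicon

The shipped `example_lexicon.csv` (14 terms) exists for tests, documentation
and simulation. It contains the handful of terms quoted in published work on
recovery-oriented documentation (`well-being`, `cname will`,
`metabolic monitoring`, `enduring`, `cname was`, `cname had`, `chronic`,
`not been able`, `is not able`) plus fixture terms; category assignments not
stated by any source are fixture choices, marked as such in the `source`
column. It is **not** a validated clinical instrument — real analyses should
supply their own validated lexicon CSV (`term,category,source`), which the
loader accepts at any size.

## Known limitations

* Matching is purely lexical: negation ("will not engage"), quotation and
  irrealis contexts are not distinguished. In the intended workflow that
  nuance is handled during human dictionary curation, not at scoring time.
* Document-level t-tests ignore clustering by author; with few authors and
  many documents the p-values are anti-conservative. A mixed-effects layer
  is an obvious extension but is out of scope.
* The initial sentence segmenter is rule-based (terminal punctuation and
  line breaks); abbreviations and decimal points can over-segment. The
  split/merge normalisation absorbs most of the resulting length noise.
* Relative change is undefined for categories absent pre-intervention;
  absolute change in percentage points is then the only reported effect.
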