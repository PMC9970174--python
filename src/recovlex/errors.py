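"""Exception hierarchy.

Input/schema problems carry exit code 2 when surfaced through the CLI;
analysis-stage problems (insufficient or degenerate data) carry exit code 3.
"""


class RecovlexError(Exception):
    """Base class for all recovlex errors."""

    exit_code = 2


class SchemaError(RecovlexError):
    """A record, table or config value does not match the documented schema."""


class DuplicateIdError(RecovlexError):
    """Two documents in one corpus share a doc_id."""


class EmptyCorpusError(RecovlexError):
    """A corpus source contained zero documents."""


class EmptyLexiconError(RecovlexError):
    """A lexicon file contained zero entries."""


class TermLengthError(RecovlexError):
    """A lexicon term falls outside the 1-3 token bound."""


class DisjointCategoryError(RecovlexError):
    """The same term appears more than once in a lexicon (categories must be disjoint)."""


class EmptySentenceError(RecovlexError):
    """An operation that requires a non-empty sentence received an empty token list."""


class EmptyDocumentError(RecovlexError):
    """A document contained no word tokens after tokenisation."""


class SpecError(RecovlexError):
    """A synthetic-corpus specification is internally inconsistent."""


class AnalysisError(RecovlexError):
    """Base for errors raised by statistical analysis rather than input parsing."""

    exit_code = 3


class InsufficientDataError(AnalysisError):
    """Too few observations for the requested statistic (e.g. one-document cohort)."""


class UndefinedRelativeChangeError(AnalysisError):
    """Relative change is undefined because the pre-intervention mean is zero."""


class UndefinedAssociationError(AnalysisError):
    """NPMI is undefined because one marginal count is zero."""


class SparseTermError(AnalysisError):
    """A term occurs in too few sentences for a stable association estimate."""
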