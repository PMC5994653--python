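"""Exception hierarchy for the trialwaste pipeline."""

from __future__ import annotations


class TrialWasteError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TrialWasteError):
    """A serialized record does not conform to the interchange schema.

    Carries the offending record id and field name in the message.
    """


class LinkageError(TrialWasteError):
    """A cross-reference (trial id, outcome id, ...) cannot be resolved."""


class CorpusValidationError(TrialWasteError):
    """A corpus violates one or more structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations[:10])
        more = "" if len(self.violations) <= 10 else f" (+{len(self.violations) - 10} more)"
        super().__init__(f"{len(self.violations)} corpus violation(s): {lines}{more}")


class RevManFormatError(TrialWasteError):
    """The supplied XML document is not a readable RevMan 5 review export."""


class CountSpecError(TrialWasteError):
    """A fixture count specification is internally inconsistent or infeasible."""


class InconsistentAnnotationError(TrialWasteError):
    """An outcome annotation falls outside the reason decision tree.

    Raised for combinations the audit has no category for, e.g. an outcome
    reported in poolable form, not flagged reported-not-pooled, yet absent
    from the meta-analysis.
    """


class MissingJudgmentError(TrialWasteError):
    """An expert judgment required by the avoidability rule is absent."""


class StructuralError(TrialWasteError):
    """The object graph lacks a required element (e.g. a review with no comparison)."""


class EmptyScopeError(TrialWasteError):
    """A tabulation or summary was requested over an empty trial scope."""
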