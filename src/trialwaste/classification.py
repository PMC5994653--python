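"""Step 2 of the audit: why is an outcome missing from the meta-analysis?

Each missing (trial, outcome) pair is assigned exactly one of five reason
categories by a deterministic decision tree over the evidence annotation:

1. a zero-event outcome (listed, but no events occurred) is an *other
   situation* — subtype ``NO_EVENT``, or ``NO_ADVERSE_EVENT`` when the
   outcome is an adverse-events outcome;
2. an outcome reported in poolable form yet absent from the meta-analysis
   is an *other situation* — subtype ``REPORTED_NOT_POOLED``;
3. registered, not planned, not reported → *inadequate planning*;
4. planned (per registry/protocol, or — absent a registration — listed in
   the publication's methods section) but not reported → *selective
   reporting*;
5. reported but not poolable → *incomplete reporting*, with or without a
   registration;
6. no registration, not reported, not listed in the methods →
   *indistinguishable* (selective reporting and inadequate planning cannot
   be separated).

Any annotation outside the tree (e.g. registered, unplanned, reported in
poolable form, not flagged reported-not-pooled, yet missing) raises
:class:`~trialwaste.errors.InconsistentAnnotationError` rather than being
silently filed somewhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Dict, List, Optional

import pandas as pd

from .errors import EmptyScopeError, InconsistentAnnotationError, TrialWasteError
from .extraction import build_contribution_matrix, select_evaluable_trials
from .model import Corpus, OutcomeAnnotation, OutcomeCategory, Planned, Poolable, TrialRecord, main_comparison


class ReasonCategory(str, enum.Enum):
    INADEQUATE_PLANNING = "inadequate_planning"
    SELECTIVE_REPORTING = "selective_reporting"
    INCOMPLETE_REPORTING = "incomplete_reporting"
    INDISTINGUISHABLE = "indistinguishable"
    OTHER = "other"


class OtherSubtype(str, enum.Enum):
    NONE = "none"
    NO_EVENT = "no_event"
    NO_ADVERSE_EVENT = "no_adverse_event"
    REPORTED_NOT_POOLED = "reported_not_pooled"


@dataclass(frozen=True)
class MissingOutcomeReason:
    category: ReasonCategory
    other_subtype: OtherSubtype = OtherSubtype.NONE

    def __post_init__(self):
        if (self.category is ReasonCategory.OTHER) == (self.other_subtype is OtherSubtype.NONE):
            raise ValueError("other_subtype must be set iff category is OTHER")


def classify_missing_outcome(
    annotation: OutcomeAnnotation,
    registration_found: bool,
    adverse_event_outcome: bool = False,
) -> MissingOutcomeReason:
    """Classify one missing outcome by the decision tree above.

    ``adverse_event_outcome`` selects the ``NO_ADVERSE_EVENT`` subtype for
    zero-event outcomes in the adverse-events category. Raises
    ``ValueError`` when the annotation is not missing at all, and
    ``InconsistentAnnotationError`` for combinations outside the tree.
    """
    if annotation.in_meta_analysis:
        raise ValueError("annotation is included in the meta-analysis; nothing to classify")
    if annotation.zero_event:
        subtype = OtherSubtype.NO_ADVERSE_EVENT if adverse_event_outcome else OtherSubtype.NO_EVENT
        return MissingOutcomeReason(ReasonCategory.OTHER, subtype)
    if annotation.reported_not_pooled:
        return MissingOutcomeReason(ReasonCategory.OTHER, OtherSubtype.REPORTED_NOT_POOLED)
    if registration_found and annotation.planned is Planned.NO and not annotation.reported:
        return MissingOutcomeReason(ReasonCategory.INADEQUATE_PLANNING)
    if not annotation.reported and (
        (registration_found and annotation.planned is Planned.YES)
        or (not registration_found and annotation.planned_in_publication_methods)
    ):
        return MissingOutcomeReason(ReasonCategory.SELECTIVE_REPORTING)
    if annotation.reported and annotation.poolable is Poolable.NO:
        return MissingOutcomeReason(ReasonCategory.INCOMPLETE_REPORTING)
    if (not registration_found and not annotation.reported
            and not annotation.planned_in_publication_methods):
        return MissingOutcomeReason(ReasonCategory.INDISTINGUISHABLE)
    raise InconsistentAnnotationError(
        "inconsistent annotation: registered={}, planned={}, reported={}, poolable={}".format(
            registration_found, annotation.planned.value, annotation.reported,
            annotation.poolable.value))


def classify_trial(trial: TrialRecord, matrix_row, outcome_ids: List[str],
                   outcome_categories: Optional[Dict[str, set]] = None,
                   ) -> Dict[str, MissingOutcomeReason]:
    """Classify every missing outcome of one evaluable trial.

    ``matrix_row`` is the trial's boolean row of the contribution matrix,
    aligned with ``outcome_ids``; included outcomes are absent from the
    returned map.
    """
    outcome_categories = outcome_categories or {}
    reasons: Dict[str, MissingOutcomeReason] = {}
    for contributes, oid in zip(matrix_row, outcome_ids):
        if contributes:
            continue
        try:
            annotation = trial.annotations[oid]
        except KeyError:
            raise TrialWasteError(
                f"trial {trial.trial_id} lacks an annotation for outcome {oid}") from None
        reasons[oid] = classify_missing_outcome(
            annotation, trial.registration_found,
            adverse_event_outcome=OutcomeCategory.ADVERSE_EVENTS
            in outcome_categories.get(oid, set()))
    return reasons


def classify_corpus(
    corpus: Corpus,
    min_year: int = 2010,
    require_accessible: bool = True,
    require_language: bool = True,
) -> pd.DataFrame:
    """Classify all missing outcomes of all evaluable trials.

    Returns a long table with one row per missing (trial, outcome) pair:
    columns review_id, trial_id, outcome_id, registered, category,
    other_subtype.
    """
    evaluable = set(select_evaluable_trials(corpus, min_year=min_year,
                                            require_accessible=require_accessible,
                                            require_language=require_language))
    rows = []
    for review in corpus.reviews:
        if not any(t.trial_id in evaluable for t in review.trials):
            continue
        matrix = build_contribution_matrix(review)
        comp = main_comparison(review)
        cats = {o.outcome_id: o.categories for o in comp.sof_outcomes}
        for trial in review.trials:
            if trial.trial_id not in evaluable:
                continue
            row = matrix.row(trial.trial_id)
            reasons = classify_trial(trial, row, matrix.outcome_ids, cats)
            for oid, reason in reasons.items():
                rows.append({"review_id": review.review_id, "trial_id": trial.trial_id,
                             "outcome_id": oid, "registered": trial.registration_found,
                             "category": reason.category.value,
                             "other_subtype": reason.other_subtype.value})
    return pd.DataFrame(rows, columns=["review_id", "trial_id", "outcome_id",
                                       "registered", "category", "other_subtype"])


REASON_ORDER = [ReasonCategory.INADEQUATE_PLANNING, ReasonCategory.SELECTIVE_REPORTING,
                ReasonCategory.INCOMPLETE_REPORTING, ReasonCategory.INDISTINGUISHABLE,
                ReasonCategory.OTHER]


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """Integer display percentage, ties rounded up (25/1000 -> 3)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is 0")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class ReasonTable:
    """Reason tabulation at outcome and trial level for one scope.

    Outcome counts partition the missing outcomes in scope; trial counts
    are coverage counts (a trial appears in every category it has at least
    one outcome in), so trial percentages may sum to more than 100.
    Exact fractions are kept; integer percentages are display values
    (half-up rounding).
    """

    scope: str  # "all_trials" or "registered_only"
    n_missing_outcomes: int
    n_trials: int
    outcome_counts: Dict[ReasonCategory, int]
    trial_counts: Dict[ReasonCategory, int]

    def outcome_fraction(self, category: ReasonCategory) -> Fraction:
        return Fraction(self.outcome_counts[category], self.n_missing_outcomes)

    def trial_fraction(self, category: ReasonCategory) -> Fraction:
        return Fraction(self.trial_counts[category], self.n_trials)

    def outcome_percent(self, category: ReasonCategory) -> int:
        return round_half_up_percent(self.outcome_counts[category], self.n_missing_outcomes)

    def trial_percent(self, category: ReasonCategory) -> int:
        return round_half_up_percent(self.trial_counts[category], self.n_trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in REASON_ORDER:
            rows.append({"category": cat.value,
                         "n_outcomes": self.outcome_counts[cat],
                         "pct_outcomes": self.outcome_percent(cat),
                         "n_trials": self.trial_counts[cat],
                         "pct_trials": self.trial_percent(cat)})
        return pd.DataFrame(rows, columns=["category", "n_outcomes", "pct_outcomes",
                                           "n_trials", "pct_trials"])


def tabulate_reasons(
    corpus: Corpus,
    scope: str = "all_trials",
    min_year: int = 2010,
    require_accessible: bool = True,
    require_language: bool = True,
    classified: Optional[pd.DataFrame] = None,
) -> ReasonTable:
    """Tabulate reason categories over evaluable trials in a scope.

    ``scope="registered_only"`` restricts both numerators and denominators
    to trials with a retrieved registration or protocol. A precomputed
    ``classify_corpus`` table may be passed to avoid reclassification.
    """
    if scope not in ("all_trials", "registered_only"):
        raise ValueError(f"unknown scope {scope!r}")
    if classified is None:
        classified = classify_corpus(corpus, min_year=min_year,
                                     require_accessible=require_accessible,
                                     require_language=require_language)
    if scope == "registered_only":
        classified = classified[classified["registered"]]
    if classified.empty:
        raise EmptyScopeError(f"no missing outcomes in scope {scope!r}")
    outcome_counts = {cat: 0 for cat in REASON_ORDER}
    trial_sets = {cat: set() for cat in REASON_ORDER}
    for rec in classified.to_dict("records"):
        cat = ReasonCategory(rec["category"])
        outcome_counts[cat] += 1
        trial_sets[cat].add(rec["trial_id"])
    return ReasonTable(
        scope=scope,
        n_missing_outcomes=len(classified),
        n_trials=classified["trial_id"].nunique(),
        outcome_counts=outcome_counts,
        trial_counts={cat: len(s) for cat, s in trial_sets.items()},
    )
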