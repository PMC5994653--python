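"""Domain model for the review/trial/outcome audit hierarchy.

A :class:`Corpus` holds systematic reviews; each review carries comparisons
with their summary-of-findings (SoF) outcomes and per-outcome meta-analyses,
plus the trial records of the main comparison. Every trial is annotated, for
every SoF outcome of the main comparison, with the evidence needed to decide
why the outcome is missing from the meta-analysis (planning, reporting,
poolability). Expert judgments of feasibility/cost/importance attach to
(trial, outcome) pairs whose missing outcome was never planned.

Structural invariants are *not* enforced at construction time; they are
checked by :func:`trialwaste.validate.validate_corpus`, which reports
violations as data so that defective corpora can be inspected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set, Tuple

from .errors import StructuralError


class OutcomeCategory(str, enum.Enum):
    """The 15 admissible outcome categories."""

    MORTALITY = "mortality"
    OTHER_CLINICAL_EVENT = "other_clinical_event"
    THERAPEUTIC_DECISION = "therapeutic_decision"
    FUNCTION = "function"
    PAIN = "pain"
    QUALITY_OF_LIFE = "quality_of_life"
    ADVERSE_EVENTS = "adverse_events"
    PHYSIOLOGICAL_VARIABLE = "physiological_variable"
    BIOLOGICAL_VARIABLE = "biological_variable"
    RADIOLOGICAL_VARIABLE = "radiological_variable"
    COMPLIANCE = "compliance"
    PROCESS = "process"
    RESOURCE_USE = "resource_use"
    COST_EFFECTIVENESS = "cost_effectiveness"
    SATISFACTION_WITH_CARE = "satisfaction_with_care"


class InterventionType(str, enum.Enum):
    PHARMACOLOGICAL = "pharmacological"
    NON_PHARMACOLOGICAL = "non_pharmacological"


class Planned(str, enum.Enum):
    """Whether the outcome appears in the registry entry or protocol.

    UNKNOWN is reserved for trials with no retrieved registration.
    """

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Poolable(str, enum.Enum):
    """Whether the reported result could enter a meta-analysis.

    NOT_APPLICABLE is reserved for outcomes with no reported result.
    """

    YES = "yes"
    NO = "no"
    NOT_APPLICABLE = "not_applicable"


class Feasibility(str, enum.Enum):
    EASY = "easy"
    MODERATELY_EASY = "moderately_easy"
    DIFFICULT = "difficult"
    IMPOSSIBLE = "impossible"


class Cost(str, enum.Enum):
    """Approximate cost of measuring the outcome, as share of total trial cost.

    no_cost <=1%, minor <=5%, moderate 5-15%, major >=15%.
    """

    NO_COST = "no_cost"
    MINOR = "minor"
    MODERATE = "moderate"
    MAJOR = "major"


class Importance(str, enum.Enum):
    MAJOR = "major"
    NON_MAJOR = "non_major"


@dataclass
class OutcomeAnnotation:
    """Per-(trial, outcome) evidence used to classify a missing outcome."""

    in_meta_analysis: bool
    planned: Planned
    planned_in_publication_methods: bool
    reported: bool
    poolable: Poolable
    zero_event: bool
    reported_not_pooled: bool


@dataclass
class SoFOutcome:
    """One row of a summary-of-findings table: an important outcome."""

    outcome_id: str
    label: str
    categories: Set[OutcomeCategory]


@dataclass
class MetaAnalysis:
    """The set of trials pooled for one SoF outcome of a comparison."""

    outcome_id: str
    contributing_trial_ids: Set[str] = field(default_factory=set)


@dataclass
class Comparison:
    comparison_id: str
    author_designated_main: bool
    sof_outcomes: List[SoFOutcome]
    meta_analyses: List[MetaAnalysis]
    trial_ids: Set[str] = field(default_factory=set)

    def outcome_ids(self) -> List[str]:
        return [o.outcome_id for o in self.sof_outcomes]

    def meta_analysis_for(self, outcome_id: str) -> Optional[MetaAnalysis]:
        for ma in self.meta_analyses:
            if ma.outcome_id == outcome_id:
                return ma
        return None

    def all_trial_ids(self) -> Set[str]:
        """Union of meta-analysis contributor sets and explicitly listed trials."""
        ids = set(self.trial_ids)
        for ma in self.meta_analyses:
            ids |= ma.contributing_trial_ids
        return ids


@dataclass
class TrialRecord:
    trial_id: str
    publication_year: int
    accessible: bool
    language_ok: bool
    registration_found: bool
    annotations: Dict[str, OutcomeAnnotation] = field(default_factory=dict)


@dataclass
class Review:
    review_id: str
    review_group: str
    intervention_type: InterventionType
    withdrawn: bool
    includes_observational: bool
    sof_mixes_interventions: bool
    comparisons: List[Comparison]
    trials: List[TrialRecord] = field(default_factory=list)

    def trial(self, trial_id: str) -> TrialRecord:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)


@dataclass
class ExpertJudgment:
    """Consensus expert judgment for one unplanned missing outcome."""

    trial_id: str
    outcome_id: str
    feasibility_trialist: Feasibility
    feasibility_patient: Feasibility
    cost: Cost
    importance: Importance


@dataclass
class Corpus:
    reviews: List[Review]
    judgments: List[ExpertJudgment] = field(default_factory=list)
    schema_version: str = "1"

    def iter_trials(self) -> Iterator[Tuple[Review, TrialRecord]]:
        for review in self.reviews:
            for trial in review.trials:
                yield review, trial

    def judgment_index(self) -> Dict[Tuple[str, str], ExpertJudgment]:
        return {(j.trial_id, j.outcome_id): j for j in self.judgments}

    def n_trials(self) -> int:
        return sum(len(r.trials) for r in self.reviews)


def main_comparison(review: Review) -> Comparison:
    """Return the main comparison of a review.

    The author-designated comparison wins when flagged; otherwise the
    comparison maximizing, lexicographically, (number of SoF outcomes,
    number of trials, earliest list position).
    """
    if not review.comparisons:
        raise StructuralError(f"review {review.review_id} has no comparison")
    for comp in review.comparisons:
        if comp.author_designated_main:
            return comp
    best = None
    best_key = None
    for pos, comp in enumerate(review.comparisons):
        key = (len(comp.sof_outcomes), len(comp.all_trial_ids()), -pos)
        if best_key is None or key > best_key:
            best, best_key = comp, key
    return best
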