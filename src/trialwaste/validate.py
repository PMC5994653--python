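"""Corpus invariant checking.

``validate_corpus`` walks the object graph and returns every violation of
the structural invariants as data (one :class:`Violation` per broken rule),
so that a defective corpus can be reported in full rather than failing on
the first problem. Readers call it and raise
:class:`~trialwaste.errors.CorpusValidationError` when the list is nonempty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from .errors import StructuralError
from .model import Corpus, Planned, Poolable, Review, main_comparison


@dataclass(frozen=True)
class Violation:
    record_id: str
    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.record_id}.{self.field}] {self.rule}: {self.message}"


def _check_review(review: Review, seen_trial_ids: set, out: List[Violation]) -> None:
    n_main = sum(1 for c in review.comparisons if c.author_designated_main)
    if n_main > 1:
        out.append(Violation(review.review_id, "comparisons", "single_main",
                             f"{n_main} comparisons flagged author_designated_main"))
    if not review.comparisons:
        out.append(Violation(review.review_id, "comparisons", "nonempty",
                             "review has no comparison"))
        return

    review_trial_ids = {t.trial_id for t in review.trials}
    for trial in review.trials:
        if trial.trial_id in seen_trial_ids:
            out.append(Violation(trial.trial_id, "trial_id", "unique_trial_id",
                                 "trial id appears more than once in the corpus"))
        seen_trial_ids.add(trial.trial_id)

    for comp in review.comparisons:
        cid = f"{review.review_id}/{comp.comparison_id}"
        if not 1 <= len(comp.sof_outcomes) <= 12:
            out.append(Violation(cid, "sof_outcomes", "sof_size_1_12",
                                 f"{len(comp.sof_outcomes)} SoF outcomes (must be 1..12)"))
        outcome_ids = [o.outcome_id for o in comp.sof_outcomes]
        if len(set(outcome_ids)) != len(outcome_ids):
            out.append(Violation(cid, "sof_outcomes", "unique_outcome_ids",
                                 "duplicate outcome ids in SoF list"))
        for outcome in comp.sof_outcomes:
            if not outcome.categories:
                out.append(Violation(outcome.outcome_id, "categories", "nonempty_categories",
                                     "outcome has no category"))
        ma_ids = [ma.outcome_id for ma in comp.meta_analyses]
        if len(set(ma_ids)) != len(ma_ids):
            out.append(Violation(cid, "meta_analyses", "one_ma_per_outcome",
                                 "more than one meta-analysis for an outcome"))
        known = set(outcome_ids)
        comp_trials = comp.all_trial_ids()
        for ma in comp.meta_analyses:
            if ma.outcome_id not in known:
                out.append(Violation(cid, "meta_analyses", "ma_outcome_in_sof",
                                     f"meta-analysis outcome {ma.outcome_id!r} not in SoF list"))
            stray = ma.contributing_trial_ids - comp.trial_ids
            if stray:
                out.append(Violation(cid, "meta_analyses", "contributors_subset",
                                     f"contributors {sorted(stray)} not among comparison trials"))
        dangling = comp_trials - review_trial_ids
        if dangling:
            out.append(Violation(cid, "trial_ids", "trials_resolve",
                                 f"trial ids {sorted(dangling)[:5]} not found in review"))

    try:
        main = main_comparison(review)
    except StructuralError:
        return
    main_outcomes = set(main.outcome_ids())
    for trial in review.trials:
        annotated = set(trial.annotations)
        extra = annotated - main_outcomes
        missing = main_outcomes - annotated
        if extra:
            out.append(Violation(trial.trial_id, "annotations", "annotations_cover_main_sof",
                                 f"annotated outcomes {sorted(extra)[:5]} not in main-comparison SoF"))
        if missing:
            out.append(Violation(trial.trial_id, "annotations", "annotations_cover_main_sof",
                                 f"main-comparison SoF outcomes {sorted(missing)[:5]} unannotated"))
        for outcome_id, ann in trial.annotations.items():
            rid = f"{trial.trial_id}/{outcome_id}"
            if trial.registration_found != (ann.planned is not Planned.UNKNOWN):
                out.append(Violation(rid, "planned", "planned_unknown_iff_unregistered",
                                     f"registration_found={trial.registration_found} with planned={ann.planned.value}"))
            if not ann.reported:
                if ann.poolable is not Poolable.NOT_APPLICABLE:
                    out.append(Violation(rid, "poolable", "unreported_not_applicable",
                                         f"reported=false with poolable={ann.poolable.value}"))
                if ann.zero_event:
                    out.append(Violation(rid, "zero_event", "unreported_no_zero_event",
                                         "reported=false with zero_event=true"))
                if ann.reported_not_pooled:
                    out.append(Violation(rid, "reported_not_pooled", "unreported_not_pooled",
                                         "reported=false with reported_not_pooled=true"))
            else:
                if ann.poolable is Poolable.NOT_APPLICABLE:
                    out.append(Violation(rid, "poolable", "reported_poolable_known",
                                         "reported=true with poolable=not_applicable"))
            if ann.reported_not_pooled and ann.poolable is not Poolable.YES:
                out.append(Violation(rid, "reported_not_pooled", "not_pooled_implies_poolable",
                                     f"reported_not_pooled=true with poolable={ann.poolable.value}"))
            if ann.in_meta_analysis and not (ann.reported and ann.poolable is Poolable.YES):
                out.append(Violation(rid, "in_meta_analysis", "included_implies_poolable",
                                     "in_meta_analysis=true requires reported=true and poolable=yes"))


def validate_corpus(corpus: Corpus) -> List[Violation]:
    """Check every structural invariant; return the list of violations.

    An empty list means the corpus is valid. Violations are data, not
    exceptions.
    """
    out: List[Violation] = []
    seen_trial_ids: set = set()
    for review in corpus.reviews:
        _check_review(review, seen_trial_ids, out)

    pair_index = set()
    for review in corpus.reviews:
        for trial in review.trials:
            for outcome_id in trial.annotations:
                pair_index.add((trial.trial_id, outcome_id))
    seen_judgments = set()
    for j in corpus.judgments:
        key = (j.trial_id, j.outcome_id)
        rid = f"{j.trial_id}/{j.outcome_id}"
        if key not in pair_index:
            out.append(Violation(rid, "judgment", "judgment_resolves",
                                 "judgment references an unknown (trial, outcome) pair"))
        if key in seen_judgments:
            out.append(Violation(rid, "judgment", "one_judgment_per_pair",
                                 "duplicate judgment for the pair"))
        seen_judgments.add(key)
    return out
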