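"""The missing-outcome reason decision tree and its tabulations."""

from __future__ import annotations

import itertools

import pytest

from trialwaste import (Corpus, OtherSubtype, Planned, Poolable, ReasonCategory,
                        classify_corpus, classify_missing_outcome, classify_trial,
                        tabulate_reasons)
from trialwaste.errors import EmptyScopeError, InconsistentAnnotationError

from conftest import make_annotation, make_review


def enumerate_admissible_annotations():
    """All admissible (annotation, registered) combinations for a missing pair.

    Admissibility mirrors the corpus invariants: planned is unknown iff
    unregistered; an unreported outcome has poolable=not_applicable and no
    zero-event / reported-not-pooled flags; reported-not-pooled requires
    poolable=yes; the pair is not in the meta-analysis.
    """
    for registered in (True, False):
        planned_options = ([Planned.YES, Planned.NO] if registered else [Planned.UNKNOWN])
        pim_options = [False] if registered else [True, False]
        for planned, pim in itertools.product(planned_options, pim_options):
            # unreported
            yield make_annotation(planned=planned, planned_in_methods=pim), registered
            # reported, all flag combinations
            for poolable, zero, rnp in itertools.product(
                    (Poolable.YES, Poolable.NO), (True, False), (True, False)):
                if rnp and poolable is not Poolable.YES:
                    continue
                yield make_annotation(planned=planned, planned_in_methods=pim,
                                      reported=True, poolable=poolable,
                                      zero_event=zero, reported_not_pooled=rnp), registered


def brute_force_reason(ann, registered):
    """Independent re-statement of the six rules as a plain if-chain."""
    if ann.zero_event:
        return ReasonCategory.OTHER
    if ann.reported_not_pooled:
        return ReasonCategory.OTHER
    if registered and ann.planned is Planned.NO and not ann.reported:
        return ReasonCategory.INADEQUATE_PLANNING
    if not ann.reported and ((registered and ann.planned is Planned.YES)
                             or (not registered and ann.planned_in_publication_methods)):
        return ReasonCategory.SELECTIVE_REPORTING
    if ann.reported and ann.poolable is Poolable.NO:
        return ReasonCategory.INCOMPLETE_REPORTING
    if (not registered and not ann.reported
            and not ann.planned_in_publication_methods):
        return ReasonCategory.INDISTINGUISHABLE
    return None  # outside the tree


class TestDecisionTree:
    @pytest.mark.parametrize("kind, registered, expected", [
        ("sr", True, ReasonCategory.SELECTIVE_REPORTING),
        ("sr", False, ReasonCategory.SELECTIVE_REPORTING),
        ("ir", False, ReasonCategory.INCOMPLETE_REPORTING),
        ("ir", True, ReasonCategory.INCOMPLETE_REPORTING),
        ("ip", True, ReasonCategory.INADEQUATE_PLANNING),
        ("indist", False, ReasonCategory.INDISTINGUISHABLE),
        ("zero", True, ReasonCategory.OTHER),
        ("rnp", False, ReasonCategory.OTHER),
    ])
    def test_canonical_examples(self, kind, registered, expected):
        review = make_review("R1", ("present", kind), registered=registered)
        ann = review.trials[0].annotations["O2"]
        reason = classify_missing_outcome(ann, registered)
        assert reason.category is expected

    def test_zero_event_subtype_tracks_adverse_events(self):
        ann = make_annotation(planned=Planned.YES, reported=True,
                              poolable=Poolable.NO, zero_event=True)
        assert classify_missing_outcome(ann, True).other_subtype is OtherSubtype.NO_EVENT
        assert classify_missing_outcome(
            ann, True, adverse_event_outcome=True).other_subtype is OtherSubtype.NO_ADVERSE_EVENT

    def test_included_annotation_is_a_precondition_error(self):
        ann = make_annotation(in_meta=True, planned=Planned.YES,
                              reported=True, poolable=Poolable.YES)
        with pytest.raises(ValueError):
            classify_missing_outcome(ann, True)

    def test_poolable_reported_but_missing_is_inconsistent(self):
        ann = make_annotation(planned=Planned.NO, reported=True, poolable=Poolable.YES)
        with pytest.raises(InconsistentAnnotationError):
            classify_missing_outcome(ann, True)

    def test_exhaustive_truth_table_matches_brute_force(self):
        """Every admissible input reaches exactly one category, and the tree
        agrees with an independent restatement of the rules."""
        n_checked = 0
        for ann, registered in enumerate_admissible_annotations():
            expected = brute_force_reason(ann, registered)
            if expected is None:
                with pytest.raises(InconsistentAnnotationError):
                    classify_missing_outcome(ann, registered)
            else:
                assert classify_missing_outcome(ann, registered).category is expected
            n_checked += 1
        assert n_checked > 20  # the enumeration is not trivially empty

    def test_registered_inputs_never_yield_indistinguishable(self):
        for ann, registered in enumerate_admissible_annotations():
            if not registered:
                continue
            try:
                reason = classify_missing_outcome(ann, registered)
            except InconsistentAnnotationError:
                continue
            assert reason.category is not ReasonCategory.INDISTINGUISHABLE


class TestTrialClassification:
    def test_map_covers_exactly_the_missing_cells(self):
        review = make_review("R1", ("present", "ip", "sr", "ir"), registered=True)
        trial = review.trials[0]
        reasons = classify_trial(trial, [True, False, False, False],
                                 ["O1", "O2", "O3", "O4"])
        assert set(reasons) == {"O2", "O3", "O4"}

    def test_fully_included_trial_yields_empty_map(self):
        review = make_review("R1", ("present", "present"))
        reasons = classify_trial(review.trials[0], [True, True], ["O1", "O2"])
        assert reasons == {}


class TestTabulation:
    def test_single_missing_outcome_is_total_share(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "sr"), registered=True)])
        table = tabulate_reasons(corpus, "all_trials")
        assert table.outcome_counts[ReasonCategory.SELECTIVE_REPORTING] == 1
        assert table.outcome_percent(ReasonCategory.SELECTIVE_REPORTING) == 100
        assert table.outcome_counts[ReasonCategory.INADEQUATE_PLANNING] == 0

    def test_multi_reason_trial_counted_in_both_trial_rows(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "ip", "ir"),
                                             registered=True)])
        table = tabulate_reasons(corpus, "all_trials")
        assert table.trial_counts[ReasonCategory.INADEQUATE_PLANNING] == 1
        assert table.trial_counts[ReasonCategory.INCOMPLETE_REPORTING] == 1
        assert sum(table.trial_counts.values()) > table.n_trials

    def test_registered_scope_has_no_indistinguishable_row(self, fixture_corpus,
                                                           fixture_classified):
        table = tabulate_reasons(fixture_corpus, "registered_only",
                                 classified=fixture_classified)
        assert table.outcome_counts[ReasonCategory.INDISTINGUISHABLE] == 0

    def test_outcome_counts_partition_the_missing_total(self, fixture_corpus,
                                                        fixture_classified):
        for scope in ("all_trials", "registered_only"):
            table = tabulate_reasons(fixture_corpus, scope, classified=fixture_classified)
            assert sum(table.outcome_counts.values()) == table.n_missing_outcomes

    def test_empty_scope_raises(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "ir"), registered=False)])
        with pytest.raises(EmptyScopeError):
            tabulate_reasons(corpus, "registered_only")

    def test_classify_corpus_covers_evaluable_trials_only(self, tiny_corpus):
        frame = classify_corpus(tiny_corpus)
        assert set(frame["trial_id"]) == {"R1-T1"}
        assert len(frame) == 1
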