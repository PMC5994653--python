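"""Shared fixtures: hand-built miniature corpora and session-wide builds."""

from __future__ import annotations

import pytest

from trialwaste import (Comparison, Corpus, Cost, ExpertJudgment, Feasibility, Importance,
                        InterventionType, MetaAnalysis, OutcomeAnnotation, OutcomeCategory,
                        Planned, Poolable, Review, SoFOutcome, TrialRecord,
                        build_fixture_from_spec, classify_corpus, generate_corpus,
                        default_config_from_marginals)


def make_annotation(in_meta=False, planned=Planned.UNKNOWN, planned_in_methods=False,
                    reported=False, poolable=Poolable.NOT_APPLICABLE,
                    zero_event=False, reported_not_pooled=False) -> OutcomeAnnotation:
    return OutcomeAnnotation(in_meta_analysis=in_meta, planned=planned,
                             planned_in_publication_methods=planned_in_methods,
                             reported=reported, poolable=poolable, zero_event=zero_event,
                             reported_not_pooled=reported_not_pooled)


def included_annotation(registered: bool) -> OutcomeAnnotation:
    return make_annotation(in_meta=True,
                           planned=Planned.YES if registered else Planned.UNKNOWN,
                           reported=True, poolable=Poolable.YES)


def make_review(review_id="R1", outcome_kinds=("present",), registered=False,
                year=2012, accessible=True, language_ok=True, trial_id=None,
                **review_flags) -> Review:
    """One single-trial review whose outcomes follow ``outcome_kinds``.

    Kinds: present, ip, sr (registered: planned; unregistered: via methods
    section), ir, indist, zero, rnp.
    """
    trial_id = trial_id or f"{review_id}-T1"
    planned_known = Planned.YES if registered else Planned.UNKNOWN
    kind_map = {
        "present": lambda: included_annotation(registered),
        "ip": lambda: make_annotation(planned=Planned.NO),
        "sr": lambda: (make_annotation(planned=Planned.YES) if registered
                       else make_annotation(planned_in_methods=True)),
        "ir": lambda: make_annotation(planned=planned_known, reported=True,
                                      poolable=Poolable.NO),
        "indist": lambda: make_annotation(),
        "zero": lambda: make_annotation(planned=planned_known, reported=True,
                                        poolable=Poolable.NO, zero_event=True),
        "rnp": lambda: make_annotation(planned=planned_known, reported=True,
                                       poolable=Poolable.YES, reported_not_pooled=True),
    }
    outcomes, mas, annotations = [], [], {}
    for i, kind in enumerate(outcome_kinds, start=1):
        oid = f"O{i}"
        outcomes.append(SoFOutcome(oid, f"outcome {i}", {OutcomeCategory.MORTALITY}))
        ann = kind_map[kind]()
        annotations[oid] = ann
        mas.append(MetaAnalysis(oid, {trial_id} if ann.in_meta_analysis else set()))
    trial = TrialRecord(trial_id=trial_id, publication_year=year, accessible=accessible,
                        language_ok=language_ok, registration_found=registered,
                        annotations=annotations)
    flags = dict(withdrawn=False, includes_observational=False, sof_mixes_interventions=False)
    flags.update(review_flags)
    return Review(review_id=review_id, review_group="test",
                  intervention_type=InterventionType.PHARMACOLOGICAL,
                  comparisons=[Comparison("C1", True, outcomes, mas, {trial_id})],
                  trials=[trial], **flags)


def easy_judgment(trial_id: str, outcome_id: str) -> ExpertJudgment:
    return ExpertJudgment(trial_id, outcome_id, Feasibility.EASY, Feasibility.EASY,
                          Cost.NO_COST, Importance.MAJOR)


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Smallest interesting corpus: 1 review, 1 trial, 2 outcomes (1 missing)."""
    return Corpus(reviews=[make_review(outcome_kinds=("present", "ir"))])


@pytest.fixture(scope="session")
def fixture_corpus() -> Corpus:
    """The deterministic reference-count corpus (built once per session)."""
    return build_fixture_from_spec()


@pytest.fixture(scope="session")
def fixture_classified(fixture_corpus):
    return classify_corpus(fixture_corpus)


@pytest.fixture(scope="session")
def synthetic_corpus() -> Corpus:
    """A mid-sized generated corpus for pipeline and oracle tests."""
    import dataclasses
    config = dataclasses.replace(default_config_from_marginals(), n_reviews=60)
    return generate_corpus(config, seed=20260925)
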