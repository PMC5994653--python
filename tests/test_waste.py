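"""Avoidability rules, trial waste levels and pooled assessment."""

from __future__ import annotations

import warnings

import pytest

from trialwaste import (Corpus, Cost, ExpertJudgment, Feasibility, Importance,
                        MissingOutcomeReason, OtherSubtype, ReasonCategory, Scenario,
                        WasteLevel, assess_trials, assess_waste, classify_corpus,
                        is_outcome_avoidable, trial_waste_level)
from trialwaste.errors import MissingJudgmentError

from conftest import easy_judgment, make_review

IP = MissingOutcomeReason(ReasonCategory.INADEQUATE_PLANNING)
SR = MissingOutcomeReason(ReasonCategory.SELECTIVE_REPORTING)
IR = MissingOutcomeReason(ReasonCategory.INCOMPLETE_REPORTING)
INDIST = MissingOutcomeReason(ReasonCategory.INDISTINGUISHABLE)
OTHER = MissingOutcomeReason(ReasonCategory.OTHER, OtherSubtype.NO_EVENT)


def judgment(feas_t=Feasibility.EASY, feas_p=Feasibility.EASY,
             cost=Cost.NO_COST, importance=Importance.MAJOR):
    return ExpertJudgment("T", "O", feas_t, feas_p, cost, importance)


class TestOutcomeAvoidability:
    @pytest.mark.parametrize("scenario", list(Scenario))
    def test_reporting_categories_always_avoidable(self, scenario):
        for reason in (SR, IR):
            avoidable, _ = is_outcome_avoidable(reason, None, scenario)
            assert avoidable

    def test_qualifying_planned_outcome_avoidable_under_planning_scenario(self):
        avoidable, code = is_outcome_avoidable(IP, judgment(),
                                               Scenario.REPORTING_PLUS_PLANNING)
        assert avoidable and code == "planning_feasible"

    @pytest.mark.parametrize("bad", [
        judgment(feas_t=Feasibility.MODERATELY_EASY),
        judgment(feas_p=Feasibility.DIFFICULT),
        judgment(cost=Cost.MODERATE),
        judgment(cost=Cost.MAJOR),
        judgment(importance=Importance.NON_MAJOR),
    ])
    def test_any_failing_clause_blocks_planning_avoidability(self, bad):
        avoidable, _ = is_outcome_avoidable(IP, bad, Scenario.REPORTING_PLUS_PLANNING)
        assert not avoidable

    def test_minor_cost_still_qualifies(self):
        avoidable, _ = is_outcome_avoidable(IP, judgment(cost=Cost.MINOR),
                                            Scenario.REPORTING_PLUS_PLANNING)
        assert avoidable

    def test_planning_never_avoidable_under_reporting_only(self):
        avoidable, _ = is_outcome_avoidable(IP, judgment(), Scenario.REPORTING_ONLY)
        assert not avoidable

    @pytest.mark.parametrize("reason", [INDIST, OTHER])
    @pytest.mark.parametrize("scenario", list(Scenario))
    def test_indistinguishable_and_other_never_avoidable(self, reason, scenario):
        avoidable, _ = is_outcome_avoidable(reason, None, scenario)
        assert not avoidable

    def test_missing_required_judgment_raises(self):
        with pytest.raises(MissingJudgmentError):
            is_outcome_avoidable(IP, None, Scenario.REPORTING_PLUS_PLANNING)


class TestTrialLevel:
    def test_all_reporting_missing_is_total(self):
        level = trial_waste_level({"O1": SR, "O2": IR}, {}, Scenario.REPORTING_ONLY)
        assert level is WasteLevel.TOTAL

    def test_indistinguishable_blocks_total_but_not_partial(self):
        level = trial_waste_level({"O1": SR, "O2": INDIST}, {}, Scenario.REPORTING_ONLY)
        assert level is WasteLevel.PARTIAL

    def test_only_other_outcomes_yield_none(self):
        level = trial_waste_level({"O1": OTHER}, {}, Scenario.REPORTING_ONLY)
        assert level is WasteLevel.NONE

    def test_other_policy_block_prevents_total(self):
        reasons = {"O1": SR, "O2": OTHER}
        assert trial_waste_level(reasons, {}, Scenario.REPORTING_ONLY) is WasteLevel.TOTAL
        assert trial_waste_level(reasons, {}, Scenario.REPORTING_ONLY,
                                 other_policy="block") is WasteLevel.PARTIAL

    def test_total_implies_partial_condition(self):
        # a total verdict requires >=1 avoidable outcome, i.e. the partial rule
        level = trial_waste_level({"O1": SR}, {}, Scenario.REPORTING_ONLY)
        assert level is WasteLevel.TOTAL  # and TOTAL subsumes PARTIAL by definition

    def test_empty_reasons_rejected(self):
        with pytest.raises(ValueError):
            trial_waste_level({}, {}, Scenario.REPORTING_ONLY)


def brute_force_assess(corpus, scenario, other_policy="exclude"):
    """Per-trial re-evaluation written directly against the rules."""
    classified = classify_corpus(corpus)
    judgment_index = corpus.judgment_index()
    verdicts = {}
    for rec in classified.to_dict("records"):
        key = rec["trial_id"]
        verdicts.setdefault(key, []).append(rec)
    n_partial = n_total = 0
    for trial_id, recs in verdicts.items():
        flags = []
        for rec in recs:
            cat = ReasonCategory(rec["category"])
            if cat is ReasonCategory.OTHER:
                if other_policy == "exclude":
                    continue
                flags.append(False)
                continue
            if cat in (ReasonCategory.SELECTIVE_REPORTING,
                       ReasonCategory.INCOMPLETE_REPORTING):
                flags.append(True)
            elif cat is ReasonCategory.INADEQUATE_PLANNING:
                if scenario is Scenario.REPORTING_ONLY:
                    flags.append(False)
                else:
                    j = judgment_index[(trial_id, rec["outcome_id"])]
                    flags.append(j.feasibility_trialist is Feasibility.EASY
                                 and j.feasibility_patient is Feasibility.EASY
                                 and j.cost in (Cost.NO_COST, Cost.MINOR)
                                 and j.importance is Importance.MAJOR)
            else:
                flags.append(False)
        if any(flags):
            n_partial += 1
            if all(flags):
                n_total += 1
    return n_partial, n_total


class TestPooledAssessment:
    @pytest.mark.parametrize("scenario", list(Scenario))
    def test_matches_brute_force_on_generated_corpus(self, synthetic_corpus, scenario):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = assess_waste(synthetic_corpus, scenario)
        partial, total = brute_force_assess(synthetic_corpus, scenario)
        assert (summary.n_partial, summary.n_total) == (partial, total)

    def test_scenario_monotonicity(self, synthetic_corpus):
        """Avoidability only grows when the planning stage is also charged."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reporting = assess_waste(synthetic_corpus, Scenario.REPORTING_ONLY)
            planning = assess_waste(synthetic_corpus, Scenario.REPORTING_PLUS_PLANNING)
        assert planning.n_partial >= reporting.n_partial
        assert planning.n_total >= reporting.n_total

    def test_no_avoidable_outcomes_means_zero_counts(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "indist"))])
        summary = assess_waste(corpus, Scenario.REPORTING_ONLY)
        assert (summary.n_partial, summary.n_total) == (0, 0)

    def test_missing_judgment_is_reported_with_the_pair(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "ip"), registered=True)])
        with pytest.raises(MissingJudgmentError, match="R1-T1"):
            assess_waste(corpus, Scenario.REPORTING_PLUS_PLANNING)
        corpus.judgments.append(easy_judgment("R1-T1", "O2"))
        summary = assess_waste(corpus, Scenario.REPORTING_PLUS_PLANNING)
        assert summary.n_total == 1

    def test_stray_judgments_warn_and_are_ignored(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "ir"))])
        corpus.judgments.append(easy_judgment("R1-T1", "O2"))  # pair classified IR
        with pytest.warns(UserWarning, match="ignored"):
            summary = assess_waste(corpus, Scenario.REPORTING_ONLY)
        assert summary.n_total == 1  # the IR outcome alone decides the verdict
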