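"""Eligibility filtering, contribution matrices and exclusion statistics."""

from __future__ import annotations

import dataclasses
import random

import numpy as np
import pytest

from trialwaste import (Corpus, EligibilityCriteria, build_contribution_matrix,
                        exclusion_stats, filter_eligible_reviews, main_comparison,
                        select_evaluable_trials, select_main_comparison)
from trialwaste.errors import EmptyScopeError

from conftest import make_review


def brute_force_exclusion(corpus: Corpus):
    """Independent recount iterating every (trial, outcome) pair directly.

    Avoids the matrix code path entirely: membership is read off the
    meta-analysis contributor sets.
    """
    fractions = []
    n_included_all = 0
    for review in corpus.reviews:
        comp = main_comparison(review)
        trial_ids = set(comp.trial_ids)
        for ma in comp.meta_analyses:
            trial_ids |= ma.contributing_trial_ids
        contributors = {ma.outcome_id: ma.contributing_trial_ids for ma in comp.meta_analyses}
        for tid in trial_ids:
            hits = 0
            for outcome in comp.sof_outcomes:
                if tid in contributors.get(outcome.outcome_id, set()):
                    hits += 1
            fractions.append(hits / len(comp.sof_outcomes))
            if hits == len(comp.sof_outcomes):
                n_included_all += 1
    return n_included_all, len(fractions) - n_included_all, float(np.mean(fractions))


class TestFilters:
    @pytest.mark.parametrize("flags, year, criterion", [
        ({"withdrawn": True}, 2012, "withdrawn"),
        ({"includes_observational": True}, 2012, "observational"),
        ({}, 2006, "trial_year"),
        ({"sof_mixes_interventions": True}, 2012, "sof_mixing"),
    ])
    def test_each_criterion_removes_and_logs(self, flags, year, criterion):
        corpus = Corpus(reviews=[make_review("R1", ("present",), year=year, **flags)])
        filtered, log = filter_eligible_reviews(corpus, EligibilityCriteria())
        assert filtered.reviews == []
        assert [e.criterion for e in log] == [criterion]

    def test_first_failing_criterion_wins(self):
        review = make_review("R1", ("present",), withdrawn=True,
                             sof_mixes_interventions=True)
        _, log = filter_eligible_reviews(Corpus(reviews=[review]))
        assert log[0].criterion == "withdrawn"

    def test_year_boundary_is_inclusive(self):
        corpus = Corpus(reviews=[make_review("R1", ("present",), year=2007)])
        filtered, _ = filter_eligible_reviews(corpus)
        assert len(filtered.reviews) == 1

    def test_disabled_criteria_keep_everything(self):
        corpus = Corpus(reviews=[make_review("R1", ("present",), year=1999,
                                             withdrawn=True)])
        filtered, log = filter_eligible_reviews(corpus, EligibilityCriteria.none())
        assert len(filtered.reviews) == 1 and log == []


class TestMainComparisonSelection:
    def _comparison(self, review_template, comparison_id, n_outcomes, n_trials, base):
        comp = make_review("X", ("present",) * n_outcomes,
                           trial_id=f"{base}-T1").comparisons[0]
        comp.comparison_id = comparison_id
        comp.author_designated_main = False
        comp.trial_ids = {f"{base}-T{i}" for i in range(1, n_trials + 1)}
        return comp

    def test_more_outcomes_beats_more_trials(self):
        review = make_review("R1", ("present",) * 5)
        review.comparisons[0].author_designated_main = False
        review.comparisons[0].comparison_id = "A"
        b = self._comparison(review, "B", 3, 12, "R1")
        review.comparisons.append(b)
        assert select_main_comparison(review) == "A"

    def test_author_designation_overrides_sizes(self):
        review = make_review("R1", ("present",) * 5)
        review.comparisons[0].author_designated_main = False
        b = self._comparison(review, "B", 1, 1, "R1")
        b.author_designated_main = True
        review.comparisons.append(b)
        assert select_main_comparison(review) == "B"

    def test_full_tie_broken_by_position(self):
        review = make_review("R1", ("present",))
        review.comparisons[0].author_designated_main = False
        twin = self._comparison(review, "Z", 1, 1, "R1")
        review.comparisons.append(twin)
        assert select_main_comparison(review) == "C1"


class TestContributionMatrix:
    def test_single_cell_true(self, tiny_corpus):
        matrix = build_contribution_matrix(tiny_corpus.reviews[0])
        assert matrix.cells.shape == (1, 2)
        assert matrix.cells[0].tolist() == [True, False]

    def test_outcome_without_meta_analysis_gives_false_column(self):
        review = make_review("R1", ("present", "present"))
        # drop the second outcome's meta-analysis entirely
        review.comparisons[0].meta_analyses = review.comparisons[0].meta_analyses[:1]
        matrix = build_contribution_matrix(review)
        assert matrix.cells[:, 1].tolist() == [False]

    def test_row_matches_membership_pattern(self):
        review = make_review("R1", ("present", "present", "present", "present"))
        review.comparisons[0].meta_analyses[2].contributing_trial_ids.clear()
        matrix = build_contribution_matrix(review)
        assert matrix.row("R1-T1").tolist() == [True, True, False, True]


class TestExclusionStats:
    def test_all_included_means_fraction_one(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "present"))])
        stats = exclusion_stats(corpus)
        assert stats.n_excluded_any == 0
        assert stats.mean_contribution_fraction == 1.0

    def test_half_contribution(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "present", "ir", "indist"))])
        stats = exclusion_stats(corpus)
        assert stats.mean_contribution_fraction == 0.5
        assert stats.n_excluded_any == 1

    def test_empty_corpus_raises(self):
        with pytest.raises(EmptyScopeError):
            exclusion_stats(Corpus(reviews=[]))

    def test_matches_brute_force_oracle_on_generated_corpora(self, synthetic_corpus):
        stats = exclusion_stats(synthetic_corpus)
        included, excluded, mean = brute_force_exclusion(synthetic_corpus)
        assert stats.n_included_all == included
        assert stats.n_excluded_any == excluded
        assert stats.mean_contribution_fraction == pytest.approx(mean, abs=1e-12)
        assert stats.n_included_all + stats.n_excluded_any == stats.n_trials

    def test_permutation_invariance(self, synthetic_corpus):
        """Shuffling trial and outcome order changes no pooled statistic."""
        import copy
        shuffled = copy.deepcopy(synthetic_corpus)
        rng = random.Random(13)
        for review in shuffled.reviews:
            rng.shuffle(review.trials)
            for comp in review.comparisons:
                order = list(range(len(comp.sof_outcomes)))
                rng.shuffle(order)
                comp.sof_outcomes = [comp.sof_outcomes[i] for i in order]
                rng.shuffle(comp.meta_analyses)
        a, b = exclusion_stats(synthetic_corpus), exclusion_stats(shuffled)
        assert (a.n_included_all, a.n_excluded_any) == (b.n_included_all, b.n_excluded_any)
        assert a.mean_contribution_fraction == pytest.approx(b.mean_contribution_fraction)

    def test_adding_a_contributor_is_monotone(self, tiny_corpus):
        """Adding a trial to a meta-analysis never lowers the mean fraction."""
        before = exclusion_stats(tiny_corpus)
        comp = tiny_corpus.reviews[0].comparisons[0]
        comp.meta_analyses[1].contributing_trial_ids.add("R1-T1")
        ann = tiny_corpus.reviews[0].trials[0].annotations["O2"]
        ann.in_meta_analysis = True
        after = exclusion_stats(tiny_corpus)
        assert after.mean_contribution_fraction >= before.mean_contribution_fraction
        assert after.n_excluded_any <= before.n_excluded_any


class TestEvaluableSelection:
    def test_recent_accessible_excluded_trial_is_selected(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "ir"), year=2010)])
        assert select_evaluable_trials(corpus) == ["R1-T1"]

    def test_year_below_threshold_not_selected(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "ir"), year=2009)])
        assert select_evaluable_trials(corpus) == []

    def test_fully_included_trial_never_selected(self):
        corpus = Corpus(reviews=[make_review("R1", ("present", "present"), year=2012)])
        assert select_evaluable_trials(corpus) == []

    @pytest.mark.parametrize("flag", ["accessible", "language_ok"])
    def test_accessibility_and_language_requirements(self, flag):
        kwargs = {flag: False}
        corpus = Corpus(reviews=[make_review("R1", ("present", "ir"), year=2012, **kwargs)])
        assert select_evaluable_trials(corpus) == []
        assert select_evaluable_trials(corpus, require_accessible=False,
                                       require_language=False) == ["R1-T1"]
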