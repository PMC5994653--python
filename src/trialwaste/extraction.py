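"""Step 1 of the audit: which trials are missing from which meta-analyses.

Given a validated corpus, this module filters reviews on eligibility
criteria, picks the main comparison of each review, builds the boolean
trial × outcome contribution matrix (cell true when the trial contributes
to the meta-analysis of that SoF outcome) and pools exclusion statistics
over reviews. The denominator of a trial's contribution fraction is every
SoF outcome of the main comparison — outcomes with no meta-analysis at all
count as missing for every trial, since SoF outcomes are important whether
or not any trial reported them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import EmptyScopeError
from .model import Corpus, Review, main_comparison


@dataclass(frozen=True)
class EligibilityCriteria:
    """Review-level eligibility filters; defaults reproduce the audit's own.

    A review survives when it is not withdrawn, includes no observational
    studies, has at least one trial published in ``min_any_trial_year`` or
    later, and its SoF table does not mix interventions. Each flag can be
    disabled independently; ``min_any_trial_year=None`` disables the year
    filter.
    """

    drop_withdrawn: bool = True
    drop_observational: bool = True
    min_any_trial_year: Optional[int] = 2007
    drop_sof_mixing_interventions: bool = True

    @classmethod
    def none(cls) -> "EligibilityCriteria":
        return cls(drop_withdrawn=False, drop_observational=False,
                   min_any_trial_year=None, drop_sof_mixing_interventions=False)


@dataclass
class ContributionMatrix:
    """Trial × SoF-outcome inclusion pattern for one main comparison."""

    review_id: str
    comparison_id: str
    trial_ids: List[str]
    outcome_ids: List[str]
    cells: np.ndarray  # boolean, shape (len(trial_ids), len(outcome_ids))

    def row(self, trial_id: str) -> np.ndarray:
        return self.cells[self.trial_ids.index(trial_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (trial, outcome) cell."""
        records = []
        for i, tid in enumerate(self.trial_ids):
            for j, oid in enumerate(self.outcome_ids):
                records.append({"review_id": self.review_id,
                                "comparison_id": self.comparison_id,
                                "trial_id": tid, "outcome_id": oid,
                                "contributes": int(self.cells[i, j])})
        return pd.DataFrame(records, columns=["review_id", "comparison_id",
                                              "trial_id", "outcome_id", "contributes"])


@dataclass
class ExclusionStats:
    """Pooled trial-level exclusion statistics.

    ``mean_contribution_fraction`` is the unweighted mean over all trials of
    the fraction of SoF outcomes each trial contributes to;
    ``mean_contribution_fraction_by_review`` first averages within each
    review, then over reviews.
    """

    n_trials: int
    n_included_all: int
    n_excluded_any: int
    mean_contribution_fraction: float
    mean_contribution_fraction_by_review: float


@dataclass
class ExclusionLogEntry:
    review_id: str
    criterion: str


def filter_eligible_reviews(
    corpus: Corpus, criteria: EligibilityCriteria = EligibilityCriteria()
) -> Tuple[Corpus, List[ExclusionLogEntry]]:
    """Apply eligibility criteria; return (filtered corpus, exclusion log).

    Criteria are evaluated in a fixed order — withdrawn, observational,
    trial-year, SoF-mixing — and the log records the first criterion each
    removed review failed. Judgments referring to removed trials are dropped.
    """
    kept: List[Review] = []
    log: List[ExclusionLogEntry] = []
    for review in corpus.reviews:
        if criteria.drop_withdrawn and review.withdrawn:
            log.append(ExclusionLogEntry(review.review_id, "withdrawn"))
            continue
        if criteria.drop_observational and review.includes_observational:
            log.append(ExclusionLogEntry(review.review_id, "observational"))
            continue
        if criteria.min_any_trial_year is not None:
            years = [t.publication_year for t in review.trials]
            if years and max(years) < criteria.min_any_trial_year:
                log.append(ExclusionLogEntry(review.review_id, "trial_year"))
                continue
        if criteria.drop_sof_mixing_interventions and review.sof_mixes_interventions:
            log.append(ExclusionLogEntry(review.review_id, "sof_mixing"))
            continue
        kept.append(review)
    kept_trials = {t.trial_id for r in kept for t in r.trials}
    judgments = [j for j in corpus.judgments if j.trial_id in kept_trials]
    return Corpus(reviews=kept, judgments=judgments,
                  schema_version=corpus.schema_version), log


def select_main_comparison(review: Review) -> str:
    """Return the comparison id of the review's main comparison.

    The author-designated comparison wins when flagged; otherwise ties are
    broken lexicographically on (number of SoF outcomes, number of trials,
    earliest list position).
    """
    return main_comparison(review).comparison_id


def build_contribution_matrix(review: Review) -> ContributionMatrix:
    """Build the trial × outcome matrix for the review's main comparison.

    Trials are the union of all meta-analysis contributor sets and the
    comparison's explicitly listed trial ids, ordered by the review's trial
    list; outcomes follow SoF order. An outcome with no meta-analysis yields
    an all-false column.
    """
    comp = main_comparison(review)
    comp_trials = comp.all_trial_ids()
    trial_ids = [t.trial_id for t in review.trials if t.trial_id in comp_trials]
    # trials referenced by the comparison but absent from the review's list
    trial_ids += sorted(comp_trials - set(trial_ids))
    outcome_ids = comp.outcome_ids()
    cells = np.zeros((len(trial_ids), len(outcome_ids)), dtype=bool)
    for j, oid in enumerate(outcome_ids):
        ma = comp.meta_analysis_for(oid)
        if ma is None:
            continue
        for i, tid in enumerate(trial_ids):
            cells[i, j] = tid in ma.contributing_trial_ids
    return ContributionMatrix(review_id=review.review_id, comparison_id=comp.comparison_id,
                              trial_ids=trial_ids, outcome_ids=outcome_ids, cells=cells)


def build_all_matrices(corpus: Corpus) -> Dict[str, ContributionMatrix]:
    """Contribution matrix per review, keyed by review id."""
    return {r.review_id: build_contribution_matrix(r) for r in corpus.reviews}


def exclusion_stats(corpus: Corpus) -> ExclusionStats:
    """Pool exclusion counts and mean contribution fractions over all reviews."""
    if not corpus.reviews:
        raise EmptyScopeError("no eligible reviews")
    fractions: List[float] = []
    by_review_means: List[float] = []
    n_included_all = 0
    for review in corpus.reviews:
        matrix = build_contribution_matrix(review)
        if matrix.cells.size == 0:
            continue
        row_fracs = matrix.cells.mean(axis=1)
        fractions.extend(row_fracs.tolist())
        by_review_means.append(float(row_fracs.mean()))
        n_included_all += int(matrix.cells.all(axis=1).sum())
    if not fractions:
        raise EmptyScopeError("no trials in any eligible review")
    n_trials = len(fractions)
    return ExclusionStats(
        n_trials=n_trials,
        n_included_all=n_included_all,
        n_excluded_any=n_trials - n_included_all,
        mean_contribution_fraction=float(np.mean(fractions)),
        mean_contribution_fraction_by_review=float(np.mean(by_review_means)),
    )


def select_evaluable_trials(
    corpus: Corpus,
    min_year: int = 2010,
    require_accessible: bool = True,
    require_language: bool = True,
) -> List[str]:
    """Trials eligible for reason classification.

    A trial qualifies when it misses at least one SoF outcome of its
    review's main comparison, was published in ``min_year`` or later, and
    (when required) its report is accessible and in a readable language.
    Order follows the corpus.
    """
    selected: List[str] = []
    for review in corpus.reviews:
        matrix = build_contribution_matrix(review)
        trial_index = {t.trial_id: t for t in review.trials}
        for i, tid in enumerate(matrix.trial_ids):
            if matrix.cells[i].all():
                continue
            trial = trial_index.get(tid)
            if trial is None:
                continue
            if trial.publication_year < min_year:
                continue
            if require_accessible and not trial.accessible:
                continue
            if require_language and not trial.language_ok:
                continue
            selected.append(tid)
    return selected
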