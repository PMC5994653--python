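"""Descriptive statistics and report generation for an audited corpus.

Proportions come with Wilson score intervals by default (a Wald interval,
truncated to [0, 1], is available); continuous summaries use the median and
quartiles with linear interpolation at positions (n-1)·{0.25, 0.5, 0.75}.
Integer display percentages are rounded half-up; exact values are retained
everywhere else. The outcome-status matrix behind the waste heat map is
exported as a long table rather than rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .classification import ReasonTable, classify_corpus, round_half_up_percent, tabulate_reasons
from .errors import EmptyScopeError
from .extraction import ExclusionStats, build_contribution_matrix, exclusion_stats
from .model import Corpus, InterventionType, OutcomeCategory, main_comparison
from .waste import Scenario, WasteSummary, assess_trials, assess_waste


@dataclass(frozen=True)
class ProportionEstimate:
    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    level: float
    method: str

    @property
    def percent(self) -> int:
        return round_half_up_percent(self.numerator, self.denominator)


def proportion_ci(numerator: int, denominator: int, method: str = "wilson",
                  level: float = 0.95) -> ProportionEstimate:
    """Binomial proportion with confidence interval.

    ``method`` is ``"wilson"`` (score interval, bounds always inside
    [0, 1]) or ``"wald"`` (normal approximation, truncated to [0, 1]).
    """
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    if method not in ("wilson", "wald"):
        raise ValueError(f"unknown method {method!r}")
    sm_method = "wilson" if method == "wilson" else "normal"
    low, high = proportion_confint(numerator, denominator, alpha=1 - level, method=sm_method)
    low = float(min(max(low, 0.0), 1.0))
    high = float(min(max(high, 0.0), 1.0))
    # degenerate boundaries are exact, not float-noise away from them
    if numerator == 0:
        low = 0.0
    if numerator == denominator:
        high = 1.0
    return ProportionEstimate(numerator=numerator, denominator=denominator,
                              point=numerator / denominator, ci_low=low, ci_high=high,
                              level=level, method=method)


def median_iqr(values) -> Tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


#: Table-1 style display order; process and resource_use print as one row.
_CATEGORY_DISPLAY_MERGE = {
    OutcomeCategory.PROCESS: "process_resource_use",
    OutcomeCategory.RESOURCE_USE: "process_resource_use",
}


def outcome_category_table(corpus: Corpus) -> pd.DataFrame:
    """Frequency of outcome categories over main-comparison SoF outcomes.

    One row per display category (process and resource_use merged);
    percentages may sum to more than 100 because an outcome can carry
    several categories. Denominator = number of SoF outcomes.
    """
    n_outcomes = 0
    counts: Dict[str, int] = {}
    for review in corpus.reviews:
        comp = main_comparison(review)
        for outcome in comp.sof_outcomes:
            n_outcomes += 1
            display = {_CATEGORY_DISPLAY_MERGE.get(c, c.value) for c in outcome.categories}
            for name in display:
                counts[name] = counts.get(name, 0) + 1
    rows = [{"category": name, "n": count,
             "pct": round_half_up_percent(count, n_outcomes)}
            for name, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["category", "n", "pct"])


@dataclass
class ExpertSummary:
    """Expert-panel shares over the judged (inadequately planned) outcomes."""

    n_judged: int
    n_critical: int
    n_critical_easy_no_cost: int

    @property
    def pct_critical(self) -> int:
        return round_half_up_percent(self.n_critical, self.n_judged)

    @property
    def pct_critical_easy_no_cost(self) -> int:
        if self.n_critical == 0:
            return 0
        return round_half_up_percent(self.n_critical_easy_no_cost, self.n_critical)


def expert_summary(corpus: Corpus, classified: Optional[pd.DataFrame] = None) -> ExpertSummary:
    """Summarize expert judgments over outcomes classified as unplanned."""
    from .model import Cost, Feasibility, Importance  # local alias for clarity

    if classified is None:
        classified = classify_corpus(corpus)
    planned_pairs = {(r["trial_id"], r["outcome_id"])
                     for r in classified.to_dict("records")
                     if r["category"] == "inadequate_planning"}
    judged = [j for j in corpus.judgments if (j.trial_id, j.outcome_id) in planned_pairs]
    critical = [j for j in judged if j.importance is Importance.MAJOR]
    easy = [j for j in critical
            if j.feasibility_trialist is Feasibility.EASY
            and j.feasibility_patient is Feasibility.EASY
            and j.cost in (Cost.NO_COST, Cost.MINOR)]
    return ExpertSummary(n_judged=len(judged), n_critical=len(critical),
                         n_critical_easy_no_cost=len(easy))


@dataclass
class SummaryReport:
    n_reviews: int
    n_trials: int
    trials_per_review: Tuple[float, float, float]  # median, q1, q3
    outcomes_per_sof: Tuple[float, float, float]
    intervention_counts: Dict[str, int]
    outcome_categories: pd.DataFrame
    exclusion: ExclusionStats
    inclusion_ci: ProportionEstimate
    exclusion_ci: ProportionEstimate
    reason_tables: Dict[str, ReasonTable]
    waste_summaries: Dict[str, WasteSummary]
    expert: Optional[ExpertSummary]

    def to_dict(self) -> dict:
        """JSON-ready view of the report (exact counts, display percents)."""
        doc = {
            "n_reviews": self.n_reviews,
            "n_trials": self.n_trials,
            "trials_per_review": {"median": self.trials_per_review[0],
                                  "q1": self.trials_per_review[1],
                                  "q3": self.trials_per_review[2]},
            "outcomes_per_sof": {"median": self.outcomes_per_sof[0],
                                 "q1": self.outcomes_per_sof[1],
                                 "q3": self.outcomes_per_sof[2]},
            "intervention_counts": self.intervention_counts,
            "outcome_categories": self.outcome_categories.to_dict("records"),
            "exclusion": {
                "n_trials": self.exclusion.n_trials,
                "n_included_all": self.exclusion.n_included_all,
                "n_excluded_any": self.exclusion.n_excluded_any,
                "pct_included_all": self.inclusion_ci.percent,
                "pct_excluded_any": self.exclusion_ci.percent,
                "ci_included_all": [self.inclusion_ci.ci_low, self.inclusion_ci.ci_high],
                "ci_excluded_any": [self.exclusion_ci.ci_low, self.exclusion_ci.ci_high],
                "mean_contribution_fraction": self.exclusion.mean_contribution_fraction,
            },
            "reason_tables": {scope: table.to_frame().to_dict("records")
                              for scope, table in self.reason_tables.items()},
            "waste": {name: {"n_evaluable": w.n_evaluable,
                             "n_partial": w.n_partial, "pct_partial": w.pct_partial,
                             "n_total": w.n_total, "pct_total": w.pct_total}
                      for name, w in self.waste_summaries.items()},
        }
        if self.expert is not None:
            doc["expert"] = {
                "n_judged": self.expert.n_judged,
                "n_critical": self.expert.n_critical,
                "pct_critical": self.expert.pct_critical,
                "n_critical_easy_no_cost": self.expert.n_critical_easy_no_cost,
                "pct_critical_easy_no_cost": self.expert.pct_critical_easy_no_cost,
            }
        return doc


def summarize_corpus(
    corpus: Corpus,
    scopes: Tuple[str, ...] = ("all_trials", "registered_only"),
    scenarios: Tuple[Scenario, ...] = (Scenario.REPORTING_ONLY, Scenario.REPORTING_PLUS_PLANNING),
    ci_method: str = "wilson",
    other_policy: str = "exclude",
    min_year: int = 2010,
) -> SummaryReport:
    """Run the full descriptive summary over an (already eligible) corpus."""
    stats = exclusion_stats(corpus)
    classified = classify_corpus(corpus, min_year=min_year)
    trials_per_review = median_iqr(len(r.trials) for r in corpus.reviews)
    outcomes_per_sof = median_iqr(len(main_comparison(r).sof_outcomes) for r in corpus.reviews)
    intervention_counts = {kind.value: 0 for kind in InterventionType}
    for review in corpus.reviews:
        intervention_counts[review.intervention_type.value] += 1

    # scopes or scenarios with no missing outcome to tabulate are omitted
    # from the report rather than failing the whole summary
    reason_tables = {}
    for scope in scopes:
        try:
            reason_tables[scope] = tabulate_reasons(corpus, scope, classified=classified)
        except EmptyScopeError:
            continue
    waste_summaries = {}
    for s in scenarios:
        try:
            waste_summaries[Scenario(s).value] = assess_waste(
                corpus, Scenario(s), other_policy=other_policy, classified=classified)
        except EmptyScopeError:
            continue
    expert = expert_summary(corpus, classified=classified) if corpus.judgments else None
    return SummaryReport(
        n_reviews=len(corpus.reviews),
        n_trials=corpus.n_trials(),
        trials_per_review=trials_per_review,
        outcomes_per_sof=outcomes_per_sof,
        intervention_counts=intervention_counts,
        outcome_categories=outcome_category_table(corpus),
        exclusion=stats,
        inclusion_ci=proportion_ci(stats.n_included_all, stats.n_trials, method=ci_method),
        exclusion_ci=proportion_ci(stats.n_excluded_any, stats.n_trials, method=ci_method),
        reason_tables=reason_tables,
        waste_summaries=waste_summaries,
        expert=expert,
    )


def export_waste_matrix(
    corpus: Corpus,
    scenario: Scenario = Scenario.REPORTING_PLUS_PLANNING,
    other_policy: str = "exclude",
    min_year: int = 2010,
) -> pd.DataFrame:
    """Outcome-status matrix of the evaluable trials, as a long table.

    One row per (trial, SoF position): status is ``present`` when the trial
    contributes to that outcome's meta-analysis, ``absent_avoidable`` when
    the outcome is missing and avoidable under the scenario, else
    ``absent``. Trials are ordered by id; positions are 1-based SoF
    positions of the main comparison.
    """
    from .waste import is_outcome_avoidable
    from .classification import MissingOutcomeReason, OtherSubtype, ReasonCategory

    classified = classify_corpus(corpus, min_year=min_year)
    reason_index = {(r["trial_id"], r["outcome_id"]):
                    MissingOutcomeReason(ReasonCategory(r["category"]),
                                         OtherSubtype(r["other_subtype"]))
                    for r in classified.to_dict("records")}
    evaluable = set(classified["trial_id"])
    judgment_index = corpus.judgment_index()
    rows = []
    for review in corpus.reviews:
        if not any(t.trial_id in evaluable for t in review.trials):
            continue
        matrix = build_contribution_matrix(review)
        for i, tid in enumerate(matrix.trial_ids):
            if tid not in evaluable:
                continue
            for position, oid in enumerate(matrix.outcome_ids, start=1):
                if matrix.cells[i, position - 1]:
                    status = "present"
                else:
                    reason = reason_index[(tid, oid)]
                    avoidable, _ = is_outcome_avoidable(
                        reason, judgment_index.get((tid, oid)), Scenario(scenario))
                    status = "absent_avoidable" if avoidable else "absent"
                rows.append({"trial_id": tid, "outcome_position": position, "status": status})
    frame = pd.DataFrame(rows, columns=["trial_id", "outcome_position", "status"])
    return frame.sort_values(["trial_id", "outcome_position"], kind="stable").reset_index(drop=True)
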