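"""Step 3 of the audit: how much of the missing-outcome waste was avoidable?

A missing outcome is *avoidable* when its reason is selective or incomplete
reporting, or — under the scenario that also charges the planning stage —
inadequate planning of an outcome the expert panel judged easy to measure
from both the trialist and patient perspective, at no or minor cost, and of
critical (major) importance. Indistinguishable outcomes are assessable but
never avoidable; *other situations* (zero events, or data already available
in poolable form) carry no trialist-attributable waste and are, under the
default policy, excluded from the per-trial denominator.

At the trial level, waste is *partial* when at least one assessable missing
outcome is avoidable and *total* when the assessable set is nonempty and
every assessable outcome is avoidable (so total implies partial).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import pandas as pd

from .classification import (MissingOutcomeReason, OtherSubtype, ReasonCategory,
                             classify_corpus, round_half_up_percent)
from .errors import EmptyScopeError, MissingJudgmentError
from .model import Corpus, Cost, ExpertJudgment, Feasibility, Importance


class Scenario(str, enum.Enum):
    """Which stages of the trial lifecycle are charged with the waste.

    ``reporting_only`` counts selective and incomplete reporting as
    avoidable; ``reporting_plus_planning`` additionally admits inadequately
    planned outcomes whose measurement the experts judged easy, cheap and
    critically important.
    """

    REPORTING_ONLY = "reporting_only"
    REPORTING_PLUS_PLANNING = "reporting_plus_planning"


class WasteLevel(str, enum.Enum):
    NONE = "none"
    PARTIAL = "partial"
    TOTAL = "total"


#: policy for OTHER-category outcomes: "exclude" drops them from the
#: assessable denominator; "block" keeps them assessable (never avoidable),
#: so their presence also blocks a total-waste verdict.
OTHER_POLICIES = ("exclude", "block")


def is_outcome_avoidable(
    reason: MissingOutcomeReason,
    judgment: Optional[ExpertJudgment],
    scenario: Scenario,
) -> Tuple[bool, str]:
    """Decide avoidability of one missing outcome; return (flag, rationale).

    The rationale code names the branch taken (e.g. ``"selective_reporting"``,
    ``"planning_feasible"``, ``"planning_not_feasible"``,
    ``"not_attributable"``). A judgment is required — and consulted — only
    for inadequately planned outcomes under ``reporting_plus_planning``.
    """
    cat = reason.category
    if cat in (ReasonCategory.SELECTIVE_REPORTING, ReasonCategory.INCOMPLETE_REPORTING):
        return True, cat.value
    if cat is ReasonCategory.INADEQUATE_PLANNING:
        if scenario is Scenario.REPORTING_ONLY:
            return False, "planning_out_of_scenario"
        if judgment is None:
            raise MissingJudgmentError(
                "expert judgment required for an inadequately planned outcome")
        feasible = (judgment.feasibility_trialist is Feasibility.EASY
                    and judgment.feasibility_patient is Feasibility.EASY
                    and judgment.cost in (Cost.NO_COST, Cost.MINOR)
                    and judgment.importance is Importance.MAJOR)
        return (True, "planning_feasible") if feasible else (False, "planning_not_feasible")
    if cat is ReasonCategory.INDISTINGUISHABLE:
        return False, "indistinguishable"
    return False, "not_attributable"  # OTHER


def trial_waste_level(
    reasons: Mapping[str, MissingOutcomeReason],
    judgments: Mapping[str, ExpertJudgment],
    scenario: Scenario,
    other_policy: str = "exclude",
    trial_id: str = "?",
) -> WasteLevel:
    """Aggregate per-outcome avoidability to a per-trial waste level.

    ``reasons`` maps outcome id -> reason for every missing outcome of the
    trial; ``judgments`` maps outcome id -> expert judgment where one
    exists. Raises :class:`MissingJudgmentError` naming the (trial, outcome)
    pair when a required judgment is absent.
    """
    if not reasons:
        raise ValueError("trial has no missing outcomes; nothing to assess")
    if other_policy not in OTHER_POLICIES:
        raise ValueError(f"unknown other_policy {other_policy!r}")
    n_assessable = 0
    n_avoidable = 0
    for oid, reason in reasons.items():
        if reason.category is ReasonCategory.OTHER and other_policy == "exclude":
            continue
        n_assessable += 1
        try:
            avoidable, _ = is_outcome_avoidable(reason, judgments.get(oid), scenario)
        except MissingJudgmentError:
            raise MissingJudgmentError(
                f"missing expert judgment for trial {trial_id!r}, outcome {oid!r}") from None
        if avoidable:
            n_avoidable += 1
    if n_avoidable == 0:
        return WasteLevel.NONE
    if n_avoidable == n_assessable:
        return WasteLevel.TOTAL
    return WasteLevel.PARTIAL


@dataclass
class WasteSummary:
    """Avoidable-waste counts over the evaluable trials, one scenario."""

    scenario: Scenario
    other_policy: str
    n_evaluable: int
    n_partial: int  # includes total trials (total is a subset of partial)
    n_total: int

    @property
    def pct_partial(self) -> int:
        return round_half_up_percent(self.n_partial, self.n_evaluable)

    @property
    def pct_total(self) -> int:
        return round_half_up_percent(self.n_total, self.n_evaluable)


def assess_trials(
    corpus: Corpus,
    scenario: Scenario,
    other_policy: str = "exclude",
    classified: Optional[pd.DataFrame] = None,
    min_year: int = 2010,
) -> pd.DataFrame:
    """Per-trial waste assessment over all evaluable trials.

    Returns one row per evaluable trial: trial_id, level, n_missing,
    n_assessable, n_avoidable. Judgments attached to pairs that are not
    classified as inadequate planning are ignored with a warning.
    """
    scenario = Scenario(scenario)
    if classified is None:
        classified = classify_corpus(corpus, min_year=min_year)
    if classified.empty:
        raise EmptyScopeError("no evaluable trials to assess")
    judgment_index = corpus.judgment_index()
    planned_pairs, classified_pairs = set(), set()
    for rec in classified.to_dict("records"):
        key = (rec["trial_id"], rec["outcome_id"])
        classified_pairs.add(key)
        if rec["category"] == ReasonCategory.INADEQUATE_PLANNING.value:
            planned_pairs.add(key)
    stray = [key for key in judgment_index
             if key in classified_pairs and key not in planned_pairs]
    if stray:
        warnings.warn(
            f"{len(stray)} expert judgment(s) attached to pairs not classified as "
            "inadequate planning were ignored", stacklevel=2)

    rows = []
    for trial_id, group in classified.groupby("trial_id", sort=True):
        reasons: Dict[str, MissingOutcomeReason] = {}
        for rec in group.to_dict("records"):
            reasons[rec["outcome_id"]] = MissingOutcomeReason(
                ReasonCategory(rec["category"]), OtherSubtype(rec["other_subtype"]))
        trial_judgments = {oid: judgment_index[(trial_id, oid)]
                           for oid in reasons if (trial_id, oid) in judgment_index}
        n_assessable = sum(1 for r in reasons.values()
                           if not (r.category is ReasonCategory.OTHER and other_policy == "exclude"))
        n_avoidable = 0
        for oid, reason in reasons.items():
            if reason.category is ReasonCategory.OTHER and other_policy == "exclude":
                continue
            try:
                avoidable, _ = is_outcome_avoidable(reason, trial_judgments.get(oid), scenario)
            except MissingJudgmentError:
                raise MissingJudgmentError(
                    f"missing expert judgment for trial {trial_id!r}, outcome {oid!r}") from None
            n_avoidable += int(avoidable)
        if n_avoidable == 0:
            level = WasteLevel.NONE
        elif n_avoidable == n_assessable:
            level = WasteLevel.TOTAL
        else:
            level = WasteLevel.PARTIAL
        rows.append({"trial_id": trial_id, "level": level.value,
                     "n_missing": len(reasons), "n_assessable": n_assessable,
                     "n_avoidable": n_avoidable})
    return pd.DataFrame(rows, columns=["trial_id", "level", "n_missing",
                                       "n_assessable", "n_avoidable"])


def assess_waste(
    corpus: Corpus,
    scenario: Scenario,
    other_policy: str = "exclude",
    classified: Optional[pd.DataFrame] = None,
    min_year: int = 2010,
) -> WasteSummary:
    """Summarize avoidable waste over the evaluable trials for one scenario."""
    scenario = Scenario(scenario)
    table = assess_trials(corpus, scenario, other_policy=other_policy,
                          classified=classified, min_year=min_year)
    n_total = int((table["level"] == WasteLevel.TOTAL.value).sum())
    n_partial = n_total + int((table["level"] == WasteLevel.PARTIAL.value).sum())
    return WasteSummary(scenario=scenario, other_policy=other_policy,
                        n_evaluable=len(table), n_partial=n_partial, n_total=n_total)
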