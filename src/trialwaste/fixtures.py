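"""Deterministic fixture corpora materialized from marginal counts.

``build_fixture_from_spec`` turns a :class:`CountSpec` — named marginal
counts of the kind a published audit reports (trials included in every
meta-analysis, evaluable trials, per-category missing-outcome and trial
counts in two registration scopes, expert-judgment counts, avoidable-waste
counts) — into a fully valid corpus whose pipeline statistics reproduce
those marginals exactly. There is no randomness: ids are systematic and
repeated builds are identical.

The construction is staged. Every evaluable trial gets its own
single-comparison review whose SoF table holds the trial's missing outcomes
plus an equal number of contributed outcomes (contribution fraction 1/2).
Within each registration scope, trials are grouped so that the category
coverage counts, the avoidability counts under both scenarios, and the
expert shares all come out right; outcome multiplicities are distributed
round-robin over the trials of each category. Non-evaluable excluded trials
are filler whose contribution fractions (1/2 or 1/3) are solved to hit the
requested mean contribution fraction. Infeasible or inconsistent counts
raise :class:`~trialwaste.errors.CountSpecError` naming the violated
constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .errors import CountSpecError
from .model import (Comparison, Corpus, Cost, ExpertJudgment, Feasibility, Importance,
                    InterventionType, MetaAnalysis, OutcomeAnnotation, OutcomeCategory,
                    Planned, Poolable, Review, SoFOutcome, TrialRecord)


@dataclass(frozen=True)
class CategoryCounts:
    """Outcome count and affected-trial count for one reason category."""

    outcomes: int
    trials: int


@dataclass(frozen=True)
class RegisteredCounts:
    n_trials: int = 156
    n_missing_outcomes: int = 461
    inadequate_planning: CategoryCounts = CategoryCounts(282, 123)
    selective_reporting: CategoryCounts = CategoryCounts(34, 23)
    incomplete_reporting: CategoryCounts = CategoryCounts(98, 64)
    other: CategoryCounts = CategoryCounts(47, 41)


@dataclass(frozen=True)
class UnregisteredCounts:
    """Marginals for evaluable trials without a retrieved registration.

    Defaults are the all-trials column minus the registered column of the
    reference audit (e.g. selective reporting 36-34=2 outcomes, 25-23=2
    trials, evidenced through the publication's methods section).
    """

    n_trials: int = 135
    n_missing_outcomes: int = 510
    selective_reporting: CategoryCounts = CategoryCounts(2, 2)
    incomplete_reporting: CategoryCounts = CategoryCounts(106, 53)
    indistinguishable: CategoryCounts = CategoryCounts(363, 122)
    other: CategoryCounts = CategoryCounts(39, 22)


@dataclass(frozen=True)
class CountSpec:
    """Named marginal counts the fixture corpus must reproduce."""

    n_trials: int = 2711
    n_included_all: int = 596
    n_recent_excluded: int = 310      # excluded trials published in recent_year or later
    n_not_evaluable: int = 19         # of those, inaccessible or wrong language
    recent_year: int = 2010
    registered: RegisteredCounts = RegisteredCounts()
    unregistered: UnregisteredCounts = UnregisteredCounts()
    # expert judgments over the inadequately planned outcomes
    n_critical: int = 221
    n_critical_easy_no_cost: int = 182
    # avoidable-waste trial counts (partial includes total)
    partial_reporting: int = 126
    total_reporting: int = 34
    partial_planning: int = 183
    total_planning: int = 86
    mean_contribution_target: float = 0.55


@dataclass
class _TrialPlan:
    registered: bool
    year: int
    accessible: bool = True
    language_ok: bool = True
    # each entry: (kind, qualifying) with kind in
    # {"ip", "sr", "ir", "other", "indist"}; qualifying used for "ip" only
    missing: List[Tuple[str, Optional[str]]] = field(default_factory=list)
    n_present: Optional[int] = None  # defaults to len(missing)


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise CountSpecError(message)


def _distribute(total: int, n: int, what: str) -> List[int]:
    """Split ``total`` outcomes over ``n`` trials, each getting at least one."""
    if n == 0:
        _require(total == 0, f"{what}: {total} outcomes but 0 trials")
        return []
    _require(total >= n, f"{what}: {total} outcomes cannot cover {n} trials")
    base, rem = divmod(total, n)
    return [base + 1] * rem + [base] * (n - rem)


def _check_spec(spec: CountSpec) -> None:
    reg, unreg = spec.registered, spec.unregistered
    n_excluded = spec.n_trials - spec.n_included_all
    _require(spec.n_included_all <= spec.n_trials,
             "n_included_all exceeds n_trials")
    _require(spec.n_recent_excluded <= n_excluded,
             "n_recent_excluded exceeds the number of excluded trials")
    _require(spec.n_not_evaluable <= spec.n_recent_excluded,
             "n_not_evaluable exceeds n_recent_excluded")
    n_evaluable = spec.n_recent_excluded - spec.n_not_evaluable
    _require(reg.n_trials + unreg.n_trials == n_evaluable,
             f"registered ({reg.n_trials}) + unregistered ({unreg.n_trials}) trials "
             f"!= evaluable trials ({n_evaluable})")
    reg_sum = (reg.inadequate_planning.outcomes + reg.selective_reporting.outcomes
               + reg.incomplete_reporting.outcomes + reg.other.outcomes)
    _require(reg_sum == reg.n_missing_outcomes,
             f"registered category outcomes sum to {reg_sum}, "
             f"not n_missing_outcomes={reg.n_missing_outcomes}")
    unreg_sum = (unreg.selective_reporting.outcomes + unreg.incomplete_reporting.outcomes
                 + unreg.indistinguishable.outcomes + unreg.other.outcomes)
    _require(unreg_sum == unreg.n_missing_outcomes,
             f"unregistered category outcomes sum to {unreg_sum}, "
             f"not n_missing_outcomes={unreg.n_missing_outcomes}")
    for scope_name, scope, cats in (
        ("registered", reg, ("inadequate_planning", "selective_reporting",
                             "incomplete_reporting", "other")),
        ("unregistered", unreg, ("selective_reporting", "incomplete_reporting",
                                 "indistinguishable", "other")),
    ):
        for cat in cats:
            cc: CategoryCounts = getattr(scope, cat)
            _require(cc.trials <= scope.n_trials,
                     f"{scope_name} {cat}: {cc.trials} trials exceed "
                     f"scope total {scope.n_trials}")
            _require(cc.outcomes >= cc.trials,
                     f"{scope_name} {cat}: {cc.outcomes} outcomes cannot cover "
                     f"{cc.trials} trials")
    n_judged = reg.inadequate_planning.outcomes
    _require(spec.n_critical <= n_judged, "n_critical exceeds judged outcomes")
    _require(spec.n_critical_easy_no_cost <= spec.n_critical,
             "n_critical_easy_no_cost exceeds n_critical")
    _require(spec.total_reporting <= spec.partial_reporting,
             "total_reporting exceeds partial_reporting")
    _require(spec.total_planning <= spec.partial_planning,
             "total_planning exceeds partial_planning")
    _require(spec.partial_reporting <= spec.partial_planning,
             "partial_planning below partial_reporting (scenario monotonicity)")
    _require(spec.total_reporting <= spec.total_planning,
             "total_planning below total_reporting (scenario monotonicity)")


def _plan_unregistered(spec: CountSpec) -> List[_TrialPlan]:
    unreg = spec.unregistered
    plans: List[_TrialPlan] = []
    n_no_indist = unreg.n_trials - unreg.indistinguishable.trials
    _require(n_no_indist >= 0, "unregistered indistinguishable trials exceed scope total")
    _require(unreg.incomplete_reporting.trials >= n_no_indist,
             "not enough unregistered incomplete-reporting trials to cover "
             "trials without an indistinguishable outcome")
    u34 = n_no_indist  # reporting-scenario total-waste trials in this scope
    # category members attached to indistinguishable trials
    n_ir_on_indist = unreg.incomplete_reporting.trials - n_no_indist
    budget = (n_ir_on_indist + unreg.selective_reporting.trials + unreg.other.trials)
    _require(budget <= unreg.indistinguishable.trials,
             "unregistered category trial counts exceed what indistinguishable "
             "trials can absorb disjointly")
    # trial order: [ir-only] [indist+ir] [indist+sr] [indist+other] [indist-only]
    for _ in range(n_no_indist):
        plans.append(_TrialPlan(registered=False, year=spec.recent_year, missing=[("ir", None)]))
    for _ in range(n_ir_on_indist):
        plans.append(_TrialPlan(registered=False, year=spec.recent_year,
                                missing=[("indist", None), ("ir", None)]))
    for _ in range(unreg.selective_reporting.trials):
        plans.append(_TrialPlan(registered=False, year=spec.recent_year,
                                missing=[("indist", None), ("sr", None)]))
    for _ in range(unreg.other.trials):
        plans.append(_TrialPlan(registered=False, year=spec.recent_year,
                                missing=[("indist", None), ("other", None)]))
    n_rest = unreg.indistinguishable.trials - budget
    for _ in range(n_rest):
        plans.append(_TrialPlan(registered=False, year=spec.recent_year,
                                missing=[("indist", None)]))
    # distribute outcome multiplicities (extras beyond the one per member)
    for kind, cc in (("sr", unreg.selective_reporting),
                     ("ir", unreg.incomplete_reporting),
                     ("indist", unreg.indistinguishable),
                     ("other", unreg.other)):
        members = [p for p in plans if any(k == kind for k, _ in p.missing)]
        counts = _distribute(cc.outcomes, len(members), f"unregistered {kind}")
        for plan, count in zip(members, counts):
            plan.missing.extend([(kind, None)] * (count - 1))
    assert u34 == n_no_indist
    return plans


def _plan_registered(spec: CountSpec, u_partial: int, u_total: int) -> List[_TrialPlan]:
    reg = spec.registered
    ip, sr, ir, oth = (reg.inadequate_planning, reg.selective_reporting,
                       reg.incomplete_reporting, reg.other)
    r_total = spec.total_reporting - u_total
    _require(r_total >= 0, "total_reporting below what unregistered trials already supply")
    srir_union = spec.partial_reporting - u_partial
    _require(srir_union >= 0, "partial_reporting below unregistered reporting-affected trials")
    overlap = sr.trials + ir.trials - srir_union
    _require(0 <= overlap <= min(sr.trials, ir.trials),
             f"registered selective/incomplete trial counts ({sr.trials}, {ir.trials}) "
             f"cannot realize a union of {srir_union} trials")
    ip_with_srir = srir_union - r_total
    _require(0 <= ip_with_srir <= ip.trials,
             "reporting-affected registered trials with inadequate planning "
             "infeasible from the supplied counts")
    ip_no_srir = ip.trials - ip_with_srir
    ipq_extra = spec.partial_planning - spec.partial_reporting
    _require(ipq_extra <= ip_no_srir,
             "partial_planning requires more planning-only trials than exist")
    n_fullq = spec.total_planning - spec.total_reporting
    _require(n_fullq <= ipq_extra,
             "total_planning requires more fully-qualifying trials than partial_planning admits")
    n_mixed = ipq_extra - n_fullq
    n_nonq_only = ip_no_srir - ipq_extra
    n_other_only = reg.n_trials - ip.trials - r_total
    _require(n_other_only >= 0,
             "registered trials cannot be partitioned: too many category trials")
    _require(n_other_only <= oth.trials,
             "registered other-situation trial count below the trials that need it")

    # qualifying / non-qualifying inadequately planned outcomes
    n_qualifying = spec.n_critical_easy_no_cost
    fullq_outcomes = n_qualifying - n_mixed
    _require(fullq_outcomes >= n_fullq,
             "qualifying planned outcomes cannot cover the fully-qualifying trials")
    nonq_total = ip.outcomes - n_qualifying
    nonq_g3 = nonq_total - n_mixed - ip_with_srir
    _require(nonq_g3 >= 0,
             "non-qualifying planned outcomes cannot staff the planning+reporting trials")

    plans: List[_TrialPlan] = []
    # group 1: all planned outcomes qualifying -> total under the planning scenario
    for count in _distribute(fullq_outcomes, n_fullq, "fully-qualifying planned"):
        plans.append(_TrialPlan(registered=True, year=spec.recent_year,
                                missing=[("ip", "q")] * count))
    # group 2: one qualifying + one non-qualifying planned outcome -> partial only
    for _ in range(n_mixed):
        plans.append(_TrialPlan(registered=True, year=spec.recent_year,
                                missing=[("ip", "q"), ("ip", "nq")]))
    # group 3: only non-qualifying planned outcomes -> no avoidable waste
    for count in _distribute(nonq_g3, n_nonq_only, "non-qualifying planned"):
        plans.append(_TrialPlan(registered=True, year=spec.recent_year,
                                missing=[("ip", "nq")] * count))
    # group 4: planning + reporting trials (one non-qualifying planned outcome each)
    sr_only = sr.trials - overlap
    a = min(sr_only, r_total)
    b = r_total - a
    _require(b <= ir.trials - overlap,
             "reporting-only total trials cannot be staffed from selective/incomplete counts")
    for _ in range(overlap):
        plans.append(_TrialPlan(registered=True, year=spec.recent_year,
                                missing=[("ip", "nq"), ("sr", None), ("ir", None)]))
    for _ in range(sr_only - a):
        plans.append(_TrialPlan(registered=True, year=spec.recent_year,
                                missing=[("ip", "nq"), ("sr", None)]))
    for _ in range((ir.trials - overlap) - b):
        plans.append(_TrialPlan(registered=True, year=spec.recent_year,
                                missing=[("ip", "nq"), ("ir", None)]))
    # group 5: reporting-only trials (no planned-missing outcome) -> total
    for _ in range(a):
        plans.append(_TrialPlan(registered=True, year=spec.recent_year,
                                missing=[("sr", None)]))
    for _ in range(b):
        plans.append(_TrialPlan(registered=True, year=spec.recent_year,
                                missing=[("ir", None)]))
    # group 6: other-situation-only trials -> nothing assessable
    for _ in range(n_other_only):
        plans.append(_TrialPlan(registered=True, year=spec.recent_year,
                                missing=[("other", None)]))

    # extra other-situation memberships go to trials whose waste verdict they
    # cannot change under either policy ordering: group 3 first, then group 4
    extra_members = oth.trials - n_other_only
    hosts = ([p for p in plans if p.missing and all(k == "ip" and q == "nq"
                                                    for k, q in p.missing)]
             + [p for p in plans if any(k == "ip" for k, _ in p.missing)
                and any(k in ("sr", "ir") for k, _ in p.missing)]
             + [p for p in plans if all(k in ("sr", "ir") for k, _ in p.missing)]
             + [p for p in plans if any(k == "ip" and q == "q" for k, q in p.missing)])
    _require(extra_members <= len(hosts),
             "registered other-situation trial count exceeds available trials")
    for plan in hosts[:extra_members]:
        plan.missing.append(("other", None))

    # outcome multiplicities for sr / ir / other beyond one per member
    for kind, cc in (("sr", sr), ("ir", ir), ("other", oth)):
        members = [p for p in plans if any(k == kind for k, _ in p.missing)]
        counts = _distribute(cc.outcomes, len(members), f"registered {kind}")
        for plan, count in zip(members, counts):
            plan.missing.extend([(kind, None)] * (count - len([1 for k, _ in plan.missing
                                                               if k == kind])))
    return plans


_CATEGORY_CYCLE = [OutcomeCategory.MORTALITY, OutcomeCategory.FUNCTION,
                   OutcomeCategory.OTHER_CLINICAL_EVENT, OutcomeCategory.PAIN,
                   OutcomeCategory.QUALITY_OF_LIFE]


def _annotation_for(kind: str, registered: bool, other_as_zero_event: bool) -> OutcomeAnnotation:
    planned_known = Planned.YES if registered else Planned.UNKNOWN
    if kind == "present":
        return OutcomeAnnotation(True, planned_known, False, True, Poolable.YES, False, False)
    if kind == "ip":
        return OutcomeAnnotation(False, Planned.NO, False, False,
                                 Poolable.NOT_APPLICABLE, False, False)
    if kind == "sr":
        if registered:
            return OutcomeAnnotation(False, Planned.YES, False, False,
                                     Poolable.NOT_APPLICABLE, False, False)
        return OutcomeAnnotation(False, Planned.UNKNOWN, True, False,
                                 Poolable.NOT_APPLICABLE, False, False)
    if kind == "ir":
        return OutcomeAnnotation(False, planned_known, False, True, Poolable.NO, False, False)
    if kind == "indist":
        return OutcomeAnnotation(False, Planned.UNKNOWN, False, False,
                                 Poolable.NOT_APPLICABLE, False, False)
    if kind == "other":
        if other_as_zero_event:
            return OutcomeAnnotation(False, planned_known, False, True, Poolable.NO, True, False)
        return OutcomeAnnotation(False, planned_known, False, True, Poolable.YES, False, True)
    raise ValueError(kind)


def build_fixture_from_spec(spec: CountSpec = CountSpec()) -> Corpus:
    """Materialize a deterministic corpus reproducing the count specification."""
    _check_spec(spec)
    unreg_plans = _plan_unregistered(spec)
    u_partial = (spec.unregistered.selective_reporting.trials
                 + spec.unregistered.incomplete_reporting.trials)
    u_total = spec.unregistered.n_trials - spec.unregistered.indistinguishable.trials
    reg_plans = _plan_registered(spec, u_partial, u_total)
    plans = reg_plans + unreg_plans
    for plan in plans:
        _require(2 * len(plan.missing) <= 12,
                 f"a trial would need {len(plan.missing)} missing outcomes; "
                 "the SoF table holds at most 12")

    # dropped (recent but not evaluable) trials: first half inaccessible,
    # the rest in an unreadable language
    n_dropped = spec.n_not_evaluable
    for i in range(n_dropped):
        inaccessible = i < (n_dropped + 1) // 2
        plans.append(_TrialPlan(registered=False, year=spec.recent_year,
                                accessible=not inaccessible,
                                language_ok=inaccessible,
                                missing=[("indist", None)]))

    # filler: older excluded trials at contribution 1/2 or 1/3 to hit the mean
    n_excluded = spec.n_trials - spec.n_included_all
    n_filler = n_excluded - spec.n_recent_excluded
    target_sum = spec.mean_contribution_target * spec.n_trials
    filler_sum = target_sum - spec.n_included_all - 0.5 * spec.n_recent_excluded
    n_half = round(6 * filler_sum - 2 * n_filler)
    n_half = max(0, min(n_filler, n_half))
    for i in range(n_filler):
        if i < n_half:
            plans.append(_TrialPlan(registered=False, year=spec.recent_year - 2,
                                    missing=[("indist", None)], n_present=1))
        else:
            plans.append(_TrialPlan(registered=False, year=spec.recent_year - 2,
                                    missing=[("indist", None), ("indist", None)], n_present=1))
    # fully included trials
    for _ in range(spec.n_included_all):
        plans.append(_TrialPlan(registered=False, year=spec.recent_year + 2,
                                missing=[], n_present=2))

    # materialize one single-comparison review per trial
    reviews: List[Review] = []
    judgments: List[ExpertJudgment] = []
    width = max(5, len(str(len(plans))))
    other_counter = 0
    nonq_critical_left = spec.n_critical - spec.n_critical_easy_no_cost
    nonq_noncritical_left = (spec.registered.inadequate_planning.outcomes
                             - spec.n_critical)
    for idx, plan in enumerate(plans, start=1):
        rid = f"R{idx:0{width}d}"
        tid = f"T{idx:0{width}d}"
        n_present = plan.n_present if plan.n_present is not None else len(plan.missing)
        kinds = ["present"] * n_present + [k for k, _ in plan.missing]
        quals = [None] * n_present + [q for _, q in plan.missing]
        outcomes, annotations, mas = [], {}, []
        for pos, (kind, qual) in enumerate(zip(kinds, quals), start=1):
            oid = f"O{pos}"
            outcomes.append(SoFOutcome(
                outcome_id=oid, label=f"outcome {pos}",
                categories={_CATEGORY_CYCLE[(pos - 1) % len(_CATEGORY_CYCLE)]}))
            if kind == "other":
                ann = _annotation_for(kind, plan.registered, other_counter % 2 == 0)
                other_counter += 1
            else:
                ann = _annotation_for(kind, plan.registered, False)
            annotations[oid] = ann
            mas.append(MetaAnalysis(outcome_id=oid,
                                    contributing_trial_ids={tid} if kind == "present" else set()))
            if kind == "ip":
                if qual == "q":
                    judgments.append(ExpertJudgment(tid, oid, Feasibility.EASY,
                                                    Feasibility.EASY, Cost.NO_COST,
                                                    Importance.MAJOR))
                elif nonq_critical_left > 0:
                    nonq_critical_left -= 1
                    judgments.append(ExpertJudgment(tid, oid, Feasibility.DIFFICULT,
                                                    Feasibility.EASY, Cost.NO_COST,
                                                    Importance.MAJOR))
                else:
                    nonq_noncritical_left -= 1
                    judgments.append(ExpertJudgment(tid, oid, Feasibility.EASY,
                                                    Feasibility.EASY, Cost.NO_COST,
                                                    Importance.NON_MAJOR))
        comparison = Comparison(comparison_id="C1", author_designated_main=True,
                                sof_outcomes=outcomes, meta_analyses=mas, trial_ids={tid})
        trial = TrialRecord(trial_id=tid, publication_year=plan.year,
                            accessible=plan.accessible, language_ok=plan.language_ok,
                            registration_found=plan.registered, annotations=annotations)
        reviews.append(Review(
            review_id=rid, review_group="synthetic",
            intervention_type=(InterventionType.PHARMACOLOGICAL if idx % 5 < 3
                               else InterventionType.NON_PHARMACOLOGICAL),
            withdrawn=False, includes_observational=False, sof_mixes_interventions=False,
            comparisons=[comparison], trials=[trial]))
    _require(nonq_noncritical_left == 0 and nonq_critical_left == 0,
             "expert-judgment counts do not add up over the planned outcomes")
    return Corpus(reviews=reviews, judgments=judgments)


def reference_count_spec() -> CountSpec:
    """The default count specification (the reference audit's marginals)."""
    return CountSpec()
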