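"""Read-only reader for a subset of RevMan 5 review XML.

RevMan (the Cochrane review-authoring software) exports a review as XML
whose ``ANALYSES_AND_DATA`` section carries comparisons, analysis outcomes
(dichotomous and continuous, optionally subgrouped) and the per-outcome
study linkage. This reader extracts that structure into a
:class:`~trialwaste.model.Review`.

SoF-table membership is not reliably machine-readable in RevMan XML, so the
caller supplies a *sidecar*: the list of analysis-outcome ids that
constitute the SoF set. Comparisons with no sidecar outcome keep all their
analysis outcomes as SoF rows. Outcome categories are seeded from a small
label-keyword heuristic (mortality / adverse events / pain / quality of
life, else other clinical event) and are meant to be curated manually
afterwards, as are the evidence annotations, which are initialized to
unknown/false with only ``in_meta_analysis`` populated from the linkage.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Set, Union

from lxml import etree

from .errors import LinkageError, RevManFormatError
from .model import (Comparison, InterventionType, MetaAnalysis, OutcomeAnnotation,
                    OutcomeCategory, Planned, Poolable, Review, SoFOutcome, TrialRecord,
                    main_comparison)

_OUTCOME_TAGS = ("DICH_OUTCOME", "CONT_OUTCOME")
_DATA_TAGS = ("DICH_DATA", "CONT_DATA")

_KEYWORD_CATEGORIES = (
    (("mortality", "death", "survival"), OutcomeCategory.MORTALITY),
    (("adverse", "side effect", "safety", "complication"), OutcomeCategory.ADVERSE_EVENTS),
    (("pain",), OutcomeCategory.PAIN),
    (("quality of life", "qol"), OutcomeCategory.QUALITY_OF_LIFE),
)


def _categories_for_label(label: str) -> Set[OutcomeCategory]:
    lowered = label.lower()
    for keywords, category in _KEYWORD_CATEGORIES:
        if any(k in lowered for k in keywords):
            return {category}
    return {OutcomeCategory.OTHER_CLINICAL_EVENT}


def _name_of(element) -> str:
    name = element.find("NAME")
    if name is not None and name.text:
        return name.text.strip()
    return element.get("ID", "")


def _study_ids(outcome_element) -> List[str]:
    ids = []
    for tag in _DATA_TAGS:
        for data in outcome_element.iter(tag):
            sid = data.get("STUDY_ID")
            if sid and sid not in ids:
                ids.append(sid)
    return ids


def read_revman_subset(source: Union[str, os.PathLike, bytes],
                       sof_sidecar: Iterable[str]) -> Review:
    """Parse a RevMan 5 review XML document into a Review.

    ``source`` is a path or raw XML bytes; ``sof_sidecar`` lists the
    analysis-outcome ids (e.g. ``"CMP-001.01"``) that make up the SoF
    table. Raises :class:`RevManFormatError` for non-RevMan XML and
    :class:`LinkageError` when a sidecar id matches no analysis outcome.
    """
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            root = etree.parse(os.fspath(source)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        if isinstance(exc, OSError):
            raise
        raise RevManFormatError(f"not parseable XML: {exc}") from exc
    if root.tag != "COCHRANE_REVIEW":
        raise RevManFormatError(f"root element is {root.tag!r}, expected 'COCHRANE_REVIEW'")

    study_years: Dict[str, int] = {}
    for study in root.iter("STUDY"):
        sid = study.get("ID")
        year = study.get("YEAR")
        if sid and year:
            try:
                study_years[sid] = int(str(year).strip()[:4])
            except ValueError:
                pass

    sidecar = list(sof_sidecar)
    seen_outcome_ids: Set[str] = set()
    comparisons: List[Comparison] = []
    for comp_el in root.iter("COMPARISON"):
        comp_id = comp_el.get("ID", f"CMP-{len(comparisons) + 1:03d}")
        outcomes: List[SoFOutcome] = []
        analyses: List[MetaAnalysis] = []
        for outcome_el in comp_el:
            if outcome_el.tag not in _OUTCOME_TAGS:
                continue
            oid = outcome_el.get("ID", "")
            label = _name_of(outcome_el)
            seen_outcome_ids.add(oid)
            outcomes.append(SoFOutcome(outcome_id=oid, label=label,
                                       categories=_categories_for_label(label)))
            analyses.append(MetaAnalysis(outcome_id=oid,
                                         contributing_trial_ids=set(_study_ids(outcome_el))))
        if not outcomes:
            continue
        in_sidecar = [o for o in outcomes if o.outcome_id in sidecar]
        if in_sidecar:
            keep = {o.outcome_id for o in in_sidecar}
            outcomes = in_sidecar
            analyses = [ma for ma in analyses if ma.outcome_id in keep]
        trial_ids: Set[str] = set()
        for ma in analyses:
            trial_ids |= ma.contributing_trial_ids
        comparisons.append(Comparison(comparison_id=comp_id, author_designated_main=False,
                                      sof_outcomes=outcomes, meta_analyses=analyses,
                                      trial_ids=trial_ids))

    missing_sidecar = [oid for oid in sidecar if oid not in seen_outcome_ids]
    if missing_sidecar:
        raise LinkageError(
            f"sidecar outcome id(s) {missing_sidecar} not found in the ANALYSES section")
    if not comparisons:
        raise RevManFormatError("no comparisons with outcomes found in ANALYSES_AND_DATA")

    review = Review(
        review_id=root.get("ID") or root.get("DOI") or "REVMAN-REVIEW",
        review_group=root.get("GROUP_ID", ""),
        intervention_type=InterventionType.PHARMACOLOGICAL,
        withdrawn=False, includes_observational=False, sof_mixes_interventions=False,
        comparisons=comparisons, trials=[])

    main = main_comparison(review)
    main_outcome_ids = main.outcome_ids()
    in_meta: Dict[str, Set[str]] = {oid: set() for oid in main_outcome_ids}
    for ma in main.meta_analyses:
        in_meta[ma.outcome_id] = set(ma.contributing_trial_ids)
    all_studies: Set[str] = set()
    for comp in comparisons:
        all_studies |= comp.all_trial_ids()
    for sid in sorted(all_studies):
        annotations = {}
        for oid in main_outcome_ids:
            included = sid in in_meta[oid]
            annotations[oid] = OutcomeAnnotation(
                in_meta_analysis=included, planned=Planned.UNKNOWN,
                planned_in_publication_methods=False, reported=included,
                poolable=Poolable.YES if included else Poolable.NOT_APPLICABLE,
                zero_event=False, reported_not_pooled=False)
        review.trials.append(TrialRecord(
            trial_id=sid, publication_year=study_years.get(sid, 0),
            accessible=True, language_ok=True, registration_found=False,
            annotations=annotations))
    return review
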