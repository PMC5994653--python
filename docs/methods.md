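# Methods

This note documents the models, conventions and design choices behind the
`trialwaste` pipeline: what each step computes, what the synthetic
substitutes for a real review corpus do and do not emulate, and where the
design was genuinely open.

## The audit model

The unit of analysis is the (trial, outcome) pair of a review's **main
comparison**, where the outcomes are the rows of the summary-of-findings
(SoF) table (1–12 rows). A pair is *missing* when the trial does not
contribute to that outcome's meta-analysis. The pipeline is purely
deterministic given a corpus: no estimation or fitting is involved; the
statistics are counts, fractions and rule-based classifications.

**Eligibility.** Reviews are filtered in a fixed order — withdrawn,
includes observational studies, no trial published in or after the
threshold year (default 2007; the bound is inclusive, "2010 or later"
means `year >= 2010` throughout), SoF table mixing interventions — and the
exclusion log records the first criterion failed. Each filter can be
disabled independently.

**Main comparison.** The author-designated comparison wins when flagged.
Otherwise the comparison maximizing, lexicographically, (number of SoF
outcomes, number of trials, earliest list position) is chosen. The
outcomes-first order was fixed because the unit of analysis is the
outcome; a conjunction like "most outcomes and most trials" does not by
itself define an order.

**Contribution matrix.** Rows are the trials of the main comparison (the
union of all meta-analysis contributor sets and the explicitly listed
trial ids — a listed trial contributing nowhere has fraction 0); columns
are all SoF outcomes, *including* outcomes with no meta-analysis at all,
which therefore count as missing for every trial. SoF outcomes are
important whether or not any trial reported them, so they belong in the
denominator. The pooled mean contribution fraction is the unweighted mean
over trials; a review-then-trial average is also exposed
(`mean_contribution_fraction_by_review`) because either reading of "every
trial contributed to X% on average" is defensible. The trial-level mean is
the default.

**Reason classification.** The decision tree is evaluated in a fixed
order: (1) zero-event → other situations (subtype `NO_EVENT`, or
`NO_ADVERSE_EVENT` for adverse-event outcomes); (2) reported-not-pooled →
other situations; (3) registered ∧ unplanned ∧ unreported → inadequate
planning; (4) planned-but-unreported → selective reporting, where
"planned" means present in the registry/protocol or — absent a
registration — listed in the publication's methods section; (5) reported ∧
not poolable → incomplete reporting, with or without registration; (6)
unregistered ∧ unreported ∧ not in the methods → indistinguishable.
Zero-event and reported-not-pooled are checked first because such outcomes
are "other situations" regardless of planning evidence. The
publication-methods evidence path (4) is what lets selective reporting be
diagnosed without a registration; without it, all-trials selective counts
could never exceed registered counts. Evidence combinations outside the
tree (e.g. registered, unplanned, reported in poolable form, not flagged
reported-not-pooled, yet missing) raise an *inconsistent annotation* error
rather than being filed silently: the taxonomy has no category for a
reviewer-side omission. Exhaustive enumeration of the admissible
annotation truth table (tested against an independent restatement of the
rules) shows every admissible input reaches exactly one category, and
registered pairs can never be indistinguishable.

**Avoidability.** Selective and incomplete reporting are always avoidable.
Inadequate planning is avoidable only under the `reporting_plus_planning`
scenario and only when the expert judgment is easy (trialist) ∧ easy
(patient) ∧ cost ∈ {no_cost, minor} ∧ importance = major ("critical
importance" maps to the scale's upper level). Indistinguishable outcomes
are assessable but never avoidable, so one indistinguishable outcome
blocks a *total* verdict but not a *partial* one. *Other situations* carry
no trialist-attributable waste (no events occurred, or the data already
exist in poolable form); by default (`other_policy="exclude"`) they are
excluded from the per-trial assessable denominator, so a trial whose only
missing outcomes are "other" has waste level *none*. The alternative
policy (`"block"`) keeps them assessable-but-unavoidable, which blocks
total verdicts; both are implemented because the trial-level handling of
these outcomes is not recoverable from published descriptions. Expert
judgments are consensus inputs per (trial, outcome) pair; the elicitation
process itself is not modelled. Judgments attached to pairs not classified
as inadequate planning are ignored with a warning.

## Descriptive statistics

* Proportions: Wilson score interval by default (bounds always within
  [0, 1]); a Wald interval truncated to [0, 1] is available. Published
  audits rarely name their interval; at integer display precision the two
  agree for the sample sizes involved, so only point percentages are used
  in acceptance checks.
* Quartiles: linear interpolation at positions (n−1)·{0.25, 0.5, 0.75}
  (numpy's default). The convention is fixed and documented because
  different conventions move printed quartiles by up to one unit.
* Display rounding: half-up to integer percent, applied only at display;
  exact fractions are kept internally. (Note: recomputing percentages from
  published count pairs occasionally disagrees with a printed percentage;
  this package always reports the value implied by the counts.)
* The per-trial outcome-status matrix behind waste heat maps is exported
  as a long table (trial × SoF position × {present, absent,
  absent_avoidable}) rather than rendered, keeping the core
  dependency-light.

## The deterministic fixture

`build_fixture_from_spec` materializes a corpus from named marginal counts
(totals, per-category outcome and trial counts in two registration scopes,
expert counts, avoidability counts). The defaults are the printed
marginals of a large published audit: 2711 trials, 596 included in all
meta-analyses, 310 recent excluded trials of which 291 evaluable and 156
registered, 971/461 missing outcomes, registered reason counts
282/34/98/47, unregistered 2/106/363/39, expert counts 221 critical of 282
judged and 182 easy-and-cheap of the 221, and avoidable-waste counts
126/34 (reporting scenario) and 183/86 (planning scenario).

The marginals underdetermine the joint assignment, so the builder uses a
staged deterministic construction. Every evaluable trial gets its own
single-comparison review whose SoF table holds the trial's missing
outcomes plus an equal number of contributed outcomes (contribution
fraction 1/2). Within each scope, trials are partitioned into groups that
pin down the category-coverage and avoidability counts — e.g. registered
trials with only fully-qualifying unplanned outcomes (totals under the
planning scenario), mixed qualifying/non-qualifying trials (partials),
reporting-only trials (totals under both scenarios) — and outcome
multiplicities are distributed round-robin within each category. The
remaining excluded trials are non-recent filler whose contribution
fractions (1/2 or 1/3) are solved in closed form to hit the requested mean
contribution fraction (0.55 by default, achieved to within 0.01 of a
percentage point at the default sizes). Infeasible count combinations
raise an error naming the violated constraint. The construction contains
no randomness; repeated builds are byte-identical after serialization.

## The synthetic generator

`generate_corpus` samples a review hierarchy top-down. Per review:
comparisons (the first is the author-designated main), SoF outcomes with
categories drawn from a weight table (a small probability of a second
category yields multi-category outcomes), and trials with publication
year, accessibility, language and registration flags. Per (trial,
outcome), the evidence chain is a directed factorization of conditional
Bernoulli draws:

    planned | registered            ~ Bern(0.60)
    reported | planned              ~ Bern(0.945)
    reported | unplanned            ~ Bern(0.312)
    poolable | reported             ~ Bern(0.854)
    zero_event | reported           ~ Bern(0.050)
    reported_not_pooled | poolable  ~ Bern(0.020)

and membership in the meta-analysis is *derived*:
`in_meta = reported ∧ poolable ∧ ¬zero_event ∧ ¬reported_not_pooled`.
For unregistered trials the methods-section flag
(`p_planned_in_methods_given_unregistered = 0.25`) plays the role of
"planned" in the reporting draw. These defaults were solved analytically
(see `implied_reason_shares`) so that the expected registered-scope reason
shares are ≈ (0.612, 0.073, 0.213, 0.102) for inadequate planning,
selective, incomplete and other — matching a published audit's
(0.61, 0.07, 0.21, 0.10) — with a per-pair missing probability of 0.45,
i.e. a mean contribution fraction of 0.55 among registered pairs. Expert
judgments are drawn for every unplanned-unreported registered pair from
independent categoricals giving P(major importance) = 0.78 and
P(easy ∧ easy ∧ ≤ minor cost) = 0.82.

Other defaults: registration rate 0.54, pharmacological share 0.60,
outcomes-per-SoF on support 1..12 with a shape whose CDF crosses
0.25/0.5/0.75 strictly inside the steps at 3, 5 and 7 (so large-sample
quartiles are exactly (3, 5, 7)), trials per main comparison from a
discretized lognormal with median 5 (approximate quartiles 3–10), recent
publication probability 0.15, accessibility and language 0.97 each.

Randomness is a single master `SeedSequence` spawning one child stream per
review, so review *k* is reproducible independently of configuration edits
that only affect later reviews.

**What the generator does not emulate.** Evidence draws are conditionally
independent across outcomes within a trial and across trials; real
reporting quality is correlated within trials and with registration
status, so generated corpora have less trial-level clustering of reasons
than real ones. Unregistered-scope reason shares match only qualitatively
(indistinguishable dominates); only the registered scope is calibrated.
Effect sizes and pooled results are not modelled — only inclusion
structure and reporting behavior. Tests passing on synthetic corpora
therefore establish the correctness of the pipeline's logic and the
recoverability of configured rates, not distributional fidelity to any
real review collection.

## RevMan import

The RevMan 5 reader extracts comparisons, dichotomous/continuous analysis
outcomes (including subgrouped data rows) and study linkage from the
`ANALYSES_AND_DATA` section. SoF membership is not reliably
machine-readable in RevMan XML, so a *sidecar* list of analysis-outcome
ids defines the SoF set; comparisons without any sidecar outcome keep all
their analysis outcomes. Outcome categories are seeded from a label
keyword heuristic (mortality, adverse events, pain, quality of life, else
other clinical event) and are intended for manual curation, as are the
evidence annotations, which start as unknown/false with only
`in_meta_analysis` populated from the linkage. Study→meta-analysis
linkage is kept for every comparison; evidence fields beyond the linkage
cannot be derived from RevMan data.

## Interchange and validation

JSON (nested, schema_version "1") is authoritative; the CSV bundle
(six tidy files) is an equivalent flat view; writes are deterministic
(sorted keys, id-ordered rows) and byte-stable. Validation returns
violations as data — record id, field, rule — and readers refuse corpora
with any violation. Checked invariants include: planned is unknown iff no
registration was found; unreported outcomes are not poolable and carry no
zero-event or reported-not-pooled flag; reported-not-pooled implies
poolable; meta-analysis membership implies reported-and-poolable;
annotations cover exactly the main comparison's SoF outcomes; contributor
sets resolve to listed trials; trial ids are corpus-unique; at most one
author-designated main comparison per review.

## Problem sizes in the test suite

Unit and property tests run on hand-built miniatures, a 60-review
generated corpus, and the full 2711-trial fixture; parameter-recovery
tests use a 500-review corpus (≈ 20 000 evidence pairs) with a 3-binomial-
SE acceptance band, a width at which the calibrated defaults sit
comfortably inside the band while genuine miscalibration of any modelled
rate would be detected.

## Known limitations

* The fixture's staged construction is complete for count specifications
  shaped like the defaults; exotic combinations (e.g. reporting-total
  demands that cannot be staffed from the category trial counts) are
  rejected rather than solved by search.
* The classification taxonomy has no category for reviewer-side
  exclusions of adequately reported, poolable outcomes; such annotations
  raise errors by design and must be resolved upstream.
* GRADE quality-of-evidence assessment, registry searching, author
  contact and the expert elicitation process are out of scope; their
  results enter only as input annotations and judgments.
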