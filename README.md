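# trialwaste

**trialwaste** audits outcome-related research waste in randomized
controlled trials (RCTs) included in systematic reviews. It is written for
meta-researchers who want to quantify how often trials fail to contribute
to the meta-analyses of the *important* outcomes — the rows of a review's
summary-of-findings (SoF) table — and how much of that failure was
avoidable.

The audit has three steps:

1. **Extraction.** For each eligible review, select the main comparison and
   build the boolean contribution matrix `C[t, o]` (trial *t* contributes
   to the meta-analysis of SoF outcome *o*). A trial's contribution
   fraction is its row mean; pooled statistics count trials included in
   all meta-analyses versus excluded from at least one.
2. **Classification.** Each missing (trial, outcome) pair is assigned one
   of five reasons by a deterministic decision tree over
   registration/protocol and reporting evidence: *inadequate planning*
   (never planned, never reported), *selective reporting* (planned, never
   reported), *incomplete reporting* (reported, but not in poolable form),
   *indistinguishable* (no registration found and nothing reported), and
   *other situations* (zero events, or results reported in poolable form
   but not pooled).
3. **Waste assessment.** A missing outcome is *avoidable* if its reason is
   selective or incomplete reporting, or — under the scenario that also
   charges the planning stage — inadequate planning of an outcome an
   expert panel judged easy to measure for both trialist and patient, at
   no or minor cost, and of critical importance. Per trial, waste is
   *partial* (≥ 1 avoidable missing outcome) or *total* (all assessable
   missing outcomes avoidable).

Corpora travel in a canonical JSON interchange format (with an equivalent
tidy CSV bundle); a read-only reader for a subset of RevMan 5 review XML
bootstraps a corpus from a Cochrane-style export. Because real review
corpora are not redistributable, the package ships two substitutes, both
first-class and tested:

* `build_fixture_from_spec(CountSpec(...))` — a deterministic corpus
  materialized from published marginal counts, whose pipeline statistics
  reproduce those counts exactly;
* `generate_corpus(GeneratorConfig(...), seed)` — a stochastic generator
  with a fully parameterized evidence chain
  (planned → reported → poolable, with zero-event and
  reported-not-pooled overrides), calibrated so its implied reason shares
  match a large published audit.

## Worked example

```python
import trialwaste as tw

corpus = tw.build_fixture_from_spec()          # deterministic 2711-trial corpus
stats = tw.exclusion_stats(corpus)
print(stats.n_included_all, stats.n_excluded_any,
      round(100 * stats.mean_contribution_fraction))
# 596 2115 55   -> 22% of trials in all meta-analyses, 78% missing from >=1,
#                  and the average trial feeds 55% of its review's meta-analyses

table = tw.tabulate_reasons(corpus, "registered_only")
print(table.to_frame().to_string(index=False))
#             category  n_outcomes  pct_outcomes  n_trials  pct_trials
#  inadequate_planning         282            61       123          79
#  selective_reporting          34             7        23          15
# incomplete_reporting          98            21        64          41
#    indistinguishable           0             0         0           0
#                other          47            10        41          26

waste = tw.assess_waste(corpus, tw.Scenario.REPORTING_PLUS_PLANNING)
print(waste.n_partial, waste.pct_partial, waste.n_total, waste.pct_total)
# 183 63 86 30   -> waste partially avoidable for 63% of evaluable trials,
#                   totally avoidable for 30%
```

Among registered trials, inadequate planning dominates (61% of missing
outcomes, 79% of trials); once expert-judged feasibility is taken into
account, almost two thirds of the evaluable trials could have contributed
to at least one more meta-analysis.

The same pipeline is scriptable from the shell:

```bash
trialwaste generate --seed 42 --out corpus.json
trialwaste extract  --in corpus.json --out stats.json --matrix-out matrices.csv
trialwaste classify --in corpus.json --out reasons.csv --table-out table.csv
trialwaste assess   --in corpus.json --scenario planning --out waste.csv
trialwaste summarize --in corpus.json --out report.json --tables-out tables/
```

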