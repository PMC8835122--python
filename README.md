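# coexmine

Market-basket analysis of occupational chemical co-exposures.

Workers are rarely exposed to a single airborne agent: a welding task may
put iron, manganese and chromium in the same breathing zone; a paint shop
mixes aromatic solvents. Occupational exposure databases (OEDBs) hold
millions of personal air measurements but record them one agent at a time,
so the mixtures have to be reconstructed. `coexmine` does that
reconstruction for industrial hygienists and exposure epidemiologists:

1. **Records** — personal air samples are validated and filtered: a study
   year window, catalog-level agent exclusions (e.g. generic dust classes
   that double-count silica or metals), per-source exclusions, a
   detected-only rule (concentration strictly above the limit of
   quantification, LOQ), and a minimum of 100 detected samples per agent.
2. **Transactions** — records are grouped into *work situations* (WS), the
   unique combinations of industrial sector × occupation × task × calendar
   year; each WS is reduced to its set of detected agents. A WS with two or
   more agents is a co-exposure situation.
3. **Frequent itemset mining** — a depth-first Eclat miner (tidset
   intersection with anti-monotone pruning) finds every agent combination
   present in at least a minimum fraction of WS. *Support* of an itemset is
   the proportion of WS (in a stated denominator universe) containing it.
4. **Association rules** — every bipartition A → C of a frequent itemset is
   scored with support = P(A ∪ C), confidence = P(C | A) =
   n(A ∪ C)/n(A), and lift = P(A ∪ C)/(P(A)·P(C)); lift 1 means A and C
   occur independently. Each rule carries the confidence of its
   complementary rule C → A (support and lift are symmetric; confidence is
   not).
5. **Subanalyses** — mining restricted to catalog-flagged carcinogens
   (IARC group 1/2A/2B), sector- and task-stratified mining (strata with
   ≥ 100 multi-agent WS; support floor max(0.1 %, 10 WS)), and a pairwise
   co-occurrence matrix with a display floor.

Because real OEDB extracts are typically not redistributable, the package
ships a synthetic-corpus generator (`coexmine.synth`) that plants known
process-profile mixtures with record-level censoring, together with
closed-form expected supports used as recovery targets in the test suite.

## Worked example

The four-WS toy database used throughout the documentation:

| WS  | agents                  |
|-----|-------------------------|
| WS1 | asbestos, lead          |
| WS2 | wood dust               |
| WS3 | benzene, ethanol, lead  |
| WS4 | asbestos, chromium, lead|

```python
import coexmine as cx

db = cx.TransactionDB.from_baskets([
    {"asbestos", "lead"},
    {"wood dust"},
    {"benzene", "ethanol", "lead"},
    {"asbestos", "chromium", "lead"},
])

print(cx.support({"asbestos", "lead"}, db, "all_ws"))
# (2, 0.5)        -> the pair occurs in 2 of 4 WS: support 50%
print(cx.confidence({"lead"}, {"asbestos"}, db))
# 0.6666666666666666   -> 2 of the 3 lead WS also have asbestos: 67%
print(cx.confidence({"asbestos"}, {"lead"}, db))
# 1.0                  -> every asbestos WS has lead: 100%
print(cx.lift({"lead"}, {"asbestos"}, db, "all_ws"))
# 1.3333333333333333   -> printed as 1.34 (displayed confidence 0.67 / 0.5)
```

A support of 50 % makes (asbestos, lead) a frequent itemset at any minimum
support up to 50 %; the lift above 1 says lead and asbestos co-occur more
often than independent agents would.

## Command line

```sh
coexmine synth --seed 1 --n-ws 5000 --out-dir corpus   # synthetic OEDB
coexmine mine --records corpus/records.csv --catalog corpus/catalog.csv \
    --out-dir out --min-support 0.001 --min-confidence 0.10
```

`mine` writes the full report bundle: filter audit, per-agent co-exposure
table, top itemsets overall and by length, rules ranked by confidence and
by lift (machine-precision and display-rounded variants), carcinogen
tables, co-occurrence matrix + heatmap, per-stratum bundles, and a
`manifest.json` with every headline count (records retained, agents, WS,
multi-agent WS, median agents per WS). `itemsets`, `rules`, `strata` and
`cooccur` run single stages with the same configuration.

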