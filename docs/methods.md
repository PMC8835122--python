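# Methods

## The analysis model

The package treats an occupational exposure database as a collection of
*transactions* in the market-basket sense. The transaction unit is the
work situation (WS): the group of personal air samples sharing an
industrial sector code, an occupation code, a task code and a calendar
year. The codes are opaque tokens — no coding-system semantics are
assumed — and equality is exact tuple equality after whitespace trimming.
A WS's basket is the set of agents detected in it at least once.

Detection is decided in exactly one predicate: a measurement counts as
detected iff its concentration is **strictly above** its limit of
quantification (LOQ). A value exactly at the LOQ is censored; the boundary
is configurable (`detect_at_loq`) but the strict reading is the default.
Concentration magnitudes play no further role: the analysis is about which
agents are present, not how much. No attempt is made to distinguish a
censored measurement from a true zero; both are "not detected".

Record filtering runs in a fixed, audited order so the audit is
reproducible and stage counts always satisfy removed + retained = input:

1. calendar-year window (default 2010–2019);
2. catalog-level agent exclusions (closed reason vocabulary:
   `generic_dust`, `duplicate_indicator`, `source_specific`, `other`) and
   per-(agent, source) exclusions;
3. detected-only restriction;
4. minimum detected-sample count per agent, default 100, applied to the
   pooled corpus (all sources together) — the natural reading when
   databases are pooled before analysis.

Rows missing any of the four WS descriptors are rejected at read time
(reason `missing_descriptor`) rather than pooled into an "unknown"
stratum, because a WS is *defined* by the full 4-tuple. Duplicate samples
are not deduplicated before the per-agent count; raw records are counted.

## Mining

**Frequent itemsets.** The miner is a from-scratch depth-first Eclat:
per-agent transaction-id sets, prefix extension by tidset intersection,
pruning on the anti-monotonicity of support. This was chosen over
breadth-first Apriori because transaction counts (10³–10⁵ WS) dwarf the
agent universe (~10²), and exact WS counts are needed for every reported
itemset; the oracle tests pin the semantics, not the algorithm. Singletons
are mined too — rule metrics and per-agent prevalence need them — even
though co-exposure reports start at two agents. Output order is total and
deterministic: WS count descending, then itemset length, then
lexicographic items.

**Support denominators.** Two universes are used in the field's reports:
all WS (the worked example) and the multi-agent universe (WS with ≥ 2
agents; the headline co-exposure tables). `denominator_kind` selects the
counting universe, restricting numerator and denominator alike so the
metric identities below hold within either universe. For itemsets of two
or more agents the WS counts coincide.

**Thresholds.** The effective absolute threshold is
`max(ceil(min_support · denominator), min_ws)`. `ceil` keeps the
fractional floor conservative (0.1 % of 10,547 → 11 WS); `min_ws` is an
absolute floor. Defaults follow the standard parameterization of this
analysis: minimum support 0.1 %, minimum rule confidence 10 %. Stratified
analyses qualify a sector or task stratum at ≥ 100 multi-agent WS and use
the floor `max(ceil(0.1 % · n_ws), 10 WS)`.

**Rules.** Every ordered bipartition (A, C) of every frequent itemset of
size ≥ 2 is a candidate rule; both sides may hold several agents. Because
all subsets of a frequent itemset are frequent at the same threshold,
antecedent and consequent counts are dictionary lookups into the mining
result — no database rescan, and zero-marginal (undefined-lift) rules can
never be emitted. Each rule records the confidence of its complement
whether or not the complement clears the confidence floor. Report tables
default to single-item consequents (the convention of published rule
tables) but the restriction is a display option, not a mining one.

## Display conventions

Machine-readable outputs are full precision. The display layer
(`coexmine.report`) rounds percentages half-up to one decimal and lift to
one decimal at or above 10, two below. Displayed lift is recomputed from
the *displayed* two-decimal confidence divided by the consequent support,
so printed metrics stay mutually consistent: a confidence of 2/3 prints as
0.67, and over a consequent support of 0.5 the printed lift is
0.67 / 0.5 = 1.34, where the full-precision 4/3 would print 1.33.

## Synthetic corpora

The generator emulates the structure of a pooled OEDB extract without
imitating any real coding system:

* 8 **process profiles** (aromatic solvents, welding metals, silica dusts,
  a ketone blend sharing one solvent with the aromatics, degreasing,
  plating, spray coating, and a deliberately rare sterilant profile at 1 %
  weight) over 30 agents; each profile has per-agent emission
  probabilities, pools of sector/occupation/task codes and a weight.
* Per WS: a profile is drawn by weight, a distinct (sector, occupation,
  task, year) key is rejection-sampled from the profile's pools, each
  profile agent is emitted independently, and each emitted (WS, agent)
  pair yields K ~ Geometric(mean 3) measurement records.
* Each record is censored independently with probability 0.48 — a typical
  share of below-LOQ results in large exposure databases — by construction
  of the concentration/LOQ pair, so the pipeline's own detection predicate
  reproduces the censoring exactly.

The WS-level detection probability has the closed form
`d = 1 − c·q / (1 − c(1−q))` with `c` the censoring probability and
`q = 1/mean_records`; the expected support of an itemset is the
profile-weight mixture of products of emission × d over its agents
(`expected_support`). These analytic values, not empirical re-runs, are
the recovery targets: the acceptance suite checks that every planted
itemset whose expectation clears the mining threshold by ≥ 3 binomial SE
is mined within 3 SE of expectation, and nothing safely below the
threshold appears. Default study size is 5,000 WS — large enough that all
non-rare planted mixtures clear the thresholds by wide margins, small
enough that the full record-level pipeline runs in seconds.

A WS-level fast path (`generate_transactions`) draws detected agent sets
directly from the same per-WS law, for Monte-Carlo studies with many
replicates; a test pins its agreement with the record-level path. The
independence null uses 200 replicates of 1,000 WS with one always-present
anchor agent (so no WS is empty and conditioning on non-emptiness cannot
induce spurious negative association) and asserts the mean pairwise lift
lies within 0.02 of 1 — a bound fixed in advance from the ratio-estimator
bias (O(1/n) ≈ 0.002 at n = 1000) and the simulation standard error
(≈ 0.002 over 200 replicates).

What the generator does **not** emulate: real sector/occupation/task
codebooks, seasonal or secular trends within the year window, correlated
sampling panels (agents measured together because they share an analytical
method), and non-random selection of workplaces into the database. Passing
recovery tests therefore demonstrate correctness of the mining machinery
under a known mixture process, not robustness to those real-data features
— in particular, panel effects can inflate lift in real data in ways the
synthetic null will never show.

## Numerical and degenerate-input choices

* Support of the empty itemset is an error, not 1.0.
* Confidence with a never-occurring antecedent, and lift with a zero
  marginal, raise instead of returning sentinel values; the rule
  generator's construction makes such rules unreachable anyway.
* Ties in every ranking break deterministically (metric desc, support
  desc, lexicographic antecedent then consequent), so report bundles are
  byte-stable across runs; a rerun test asserts byte identity.
* The carcinogen-restricted universe (denominators included) is always
  recomputed from the restricted transactions, never hard-coded.
* An empty transaction database is valid output of grouping (empty input)
  but an error for the summary and co-occurrence operations.
* The co-occurrence export masks sub-floor pairs (missing values) rather
  than zeroing them, so masking is reversible.

## Known limitations

* The rule generator enumerates all 2^k − 2 bipartitions per itemset; fine
  for the itemset sizes these data produce (≤ ~8 agents), not for dense
  baskets with dozens of items.
* `summarize_coexposure` reports exact per-agent record counts only when
  the record list is supplied alongside the transaction database.
* No closed/maximal itemset condensation is offered; the analysis reports
  all frequent itemsets.
* No statistical inference across strata — the stratified output is
  descriptive, matching practice in this analysis type.
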