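# Methods

## Transactions and the mining model

One station-month is one transaction. Each retained attribute contributes
exactly one item `attr=category` with category ∈ {low, medium, high}, so a
transaction over six predictors plus yield always has seven items. Mining is
per zone with N equal to that zone's transaction count: the cutpoints, and
therefore the meaning of every item, are zone-specific, so pooling
transactions across zones would mix incomparable categories. With 26 years of
months, N = 312 per zone.

Support, confidence and lift follow the standard definitions (see README).
Counts stay integers throughout the miner; fractional support is computed
once, at the boundary, to avoid float accumulation. The fractional minimum
support s is converted to a count threshold ⌈s·N⌉ — the conservative reading
under which a reported support fraction is always ≥ s. A minimum support
above 1 is legal and simply yields an empty result.

## Discretization

Cutpoints are mean − sd and mean + sd per zone and attribute, with the sample
(n−1) standard deviation. Cutpoint values belong to the extreme categories
(≤ low cut → low, ≥ high cut → high); the medium band is open on both sides.
For the degenerate table low cut = high cut the ≤ test runs first, so the
shared cutpoint classifies as low — an arbitrary but fixed and documented
tie-break. NaN values are rejected rather than silently categorised.

A consequence worth knowing: under any roughly symmetric distribution the
high band holds ~16% of a zone's months, so `Yield=high` alone sits *below* a
0.2 support floor. On data without structure linking climate categories to
yield, no rule with that consequent can be frequent, and the run cleanly
reports zero rules. Rules only emerge when the high-yield months cluster with
particular climate categories — which is exactly what the method is for, and
what the planted-rule tests emulate. Relatedly, a reported rule with
confidence 1 can only have lift 1 if every transaction is high-yield; on full
zones the two cannot hold simultaneously, so this package reports lift
exactly as defined and does not expect it to equal 1 for perfect-confidence
rules.

## Correlation filter

Pairwise Pearson |r| over the pooled (all-zone) monthly records, predictors
only; the response is never dropped. While any pair exceeds the threshold
(default 0.8), the predictor involved in the most offending pairs is removed,
ties broken by a fixed keep-priority order Tmin > Tmax > Umax > Umin > RR >
Sun > ET (the later one goes). This makes the outcome deterministic and, on
data where Umin tracks both Umax and Tmax, reproduces the canonical result
that Umin alone is removed. Zero-variance attributes have undefined
correlations; they are kept and logged. Absolute r is used: a filter on
signed r would be indistinguishable on the motivating data, where the strong
pairs are positive.

## FP-Growth engine

Two passes over the transaction stream: pass 1 counts item frequencies and
drops items below the support-count floor; pass 2 inserts each transaction's
surviving items, sorted by global frequency descending with ascending label
as the tie-break, sharing prefix nodes. The tie-break makes trees — and hence
all downstream output files — identical across runs and platforms. Mining
walks the header table in ascending frequency, assembles each item's
conditional pattern base from its node-link chain, builds the conditional
tree and recurses; a tree degenerated to a single path is enumerated
combinatorially (each subset's count is its deepest node's count). No
parallelism: the intended inputs are ≤ ~312 transactions over ≤ 21 items.

The independent oracle is a deliberately separate levelwise Apriori
enumerator (candidate join, downward-closure prune, full scan per level)
guarded to ≤ 25 distinct frequent items. The suite checks exact agreement of
itemsets *and* counts on 200+ random databases.

## Rule generation and ranking

Only single-item consequents are generated: the analysis asks which climate
combinations imply `Yield=high`, so the general multi-consequent enumeration
would be dead code. For every frequent itemset containing the consequent, the
rule (Z ∖ {c}) ⇒ {c} is emitted with metrics from exact counts; empty
antecedents are skipped. Filtering keeps rules with ≥ 3 antecedent items,
confidence ≥ 0.8 and lift ≥ 1 (all inclusive). "Most relevant" is
operationalised as the lexicographic sort (confidence, lift, support)
descending with sorted antecedent labels as a total tie-break, truncated to
the top 5 — a deterministic reading of a ranking that is otherwise
under-specified. The lift identity lift·support(X)·support(Y) = support is
checked to 1e-9 relative tolerance in the tests.

## Synthetic generator

The generator emulates three zones × 26 years × 12 months. Attributes are
independent truncated normals; the mean/sd per attribute come from inverting
a threshold table (mean = midpoint, sd = half-width of the medium band), so
the built-in zone tables double as generator calibration. Truncation bounds
are physical: RR, Sun, ET and yield ≥ 0, humidities in [0, 100], temperatures
unbounded. Truncation shifts realised moments; the shift is accepted, and
recovery tests compare against the truncated distribution's theoretical
mean ± sd (via `scipy.stats.truncnorm`) with a 3-standard-error tolerance,
SE(cutpoint) = sd·√(1/n + 1/(2(n−1))).

Minimum humidity is by default 0.9·Umax + N(0, 2) clipped to [0, 100], giving
the > 0.8 correlation the filter stage exists to catch; a switch draws it
independently instead. One master seed drives everything; per-zone streams
are spawned from it, so adding or reordering zones never perturbs another
zone's draws.

The *daily* generator serves the aggregation path. Because the profiles
describe monthly-mean variability, each month first receives a latent monthly
mean drawn from the profile and each day adds noise of scale 0.5·sd around
it, re-truncated to the physical range; monthly averages then recover the
profile's mean and (within ~0.5%) its sd. Drawing days directly from the
monthly distribution would shrink monthly-mean spread by √30 and let
between-zone mean differences dominate the pooled correlations, which is not
what station data look like. What the generator still does *not* emulate:
seasonality, autocorrelation, spatial structure, within-zone climate–yield
dependence beyond planted rules, and the fact that real disaggregated yield
is constant within a year. Passing tests therefore certify the machinery —
counts, filters, exact mining, metric identities, recovery — not any
agronomic claim about real stations.

### Rule planting

For targets (s, c) on n records, k = ⌈s·n⌉ records receive the full itemset
(values sampled inside each category's numeric band, uniformly, with a 5%
interior margin for the open medium band), m − k further records receive the
antecedent only (consequent forced to another category), where m ∈ [k, n] is
the integer making k/m closest to c; every remaining record has its first
antecedent attribute forced *out* of its planted category, so the antecedent
count is exactly m and the itemset count exactly k. If no m brings k/m within
1/n of c — a real possibility, e.g. k = 78, c = 0.8 has nearest ratios 78/97
and 78/98, both farther than 1/312 — planting refuses with an infeasibility
error rather than silently missing the target.

Recovery is verified through the pipeline run with the *same* threshold table
used for planting (the pipeline's default recomputes cutpoints from the data,
which would redefine the categories the rule was planted in; `RunConfig`
supports both modes).

## Numerical and I/O choices

CSV dialect is fixed (comma, header, dot decimal, UTF-8, LF) and every sort
order is total, so reruns are byte-identical and the manifest hashes are a
meaningful regression fixture. Rules and itemsets use pipe-delimited columns
with ";"-joined sorted item lists; rule metrics print with three decimals.
Transactions are written in basket format (one line per transaction,
space-separated items, sorted). Problem sizes in the tests and acceptance
script — 312-record zones, 200 random databases of ≤ 40 transactions over
≤ 8 items — are the scales the method targets; everything completes in
seconds.

## Known limitations

* Pooled correlations on multi-zone data retain a between-zone component
  (up to |r| ≈ 0.5 under the built-in calibration); the filter is only
  meant to catch near-collinear pairs, not to remove zone structure.
* The brute-force oracle is exponential by design and guarded at 25 items.
* The generator's independence assumption means realistic yield–climate
  dependence exists only where planted.
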