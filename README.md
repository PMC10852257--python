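# agrorules

Association-rule mining between monthly climate conditions and tomato yield
in Benin's three agro-ecological zones (Sudanian / Kandi, Sudano-Guinean /
Savè, Guinean / Cotonou), built around a from-scratch FP-Growth engine.

## The problem and who this is for

Agro-meteorologists and crop modellers often want to know which *combinations*
of climate conditions co-occur with good harvests, not just which single
variable correlates with yield. This package frames that question as market
basket analysis: every station-month becomes a *transaction* whose items are
categorical statements such as `ET=low` or `Yield=high`, and frequent-pattern
mining surfaces the climate-category combinations that reliably imply the
high-yield category.

The pipeline:

1. **Aggregate** daily station records (Tmin, Tmax, Umin, Umax, RR, Sun, ET)
   to monthly means; disaggregate the annual tomato yield to a constant
   annual/12 per month, joined on (zone, year).
2. **Filter** collinear predictors: pairwise Pearson |r| on the pooled monthly
   records; from every pair above 0.8 one member is dropped (in the canonical
   data, minimum humidity tracks maximum humidity and goes).
3. **Discretize** each attribute per zone into `low` / `medium` / `high` at
   the cutpoints mean − sd and mean + sd (value ≤ low cut → low,
   ≥ high cut → high, open interval → medium). Built-in tables for the three
   Benin zones ship in `agrorules.zones`.
4. **Mine** frequent itemsets per zone with FP-Growth at minimum support 0.2.
5. **Rank rules** X ⇒ {Yield=high} by the standard metrics

   * support(X ⇒ Y) = count(X ∪ Y) / N
   * confidence(X ⇒ Y) = count(X ∪ Y) / count(X)
   * lift(X ⇒ Y) = confidence / (count(Y) / N)

   keeping rules with ≥ 3 antecedents, confidence ≥ 0.8 and lift ≥ 1, and
   reporting the top 5 by (confidence, lift, support) descending.

Because the underlying station records are not publicly deposited, the package
includes a calibrated synthetic generator (`agrorules.synthetic`): truncated
normal draws per attribute whose mean/sd are reconstructed from the published
per-zone threshold tables, with the option to *plant* rules at an exact
support and confidence for recovery testing.

## Worked example

Plant the association {ET=low, Tmin=medium, Umax=high} ⇒ {Yield=high} at
support 0.25 and confidence 1.0 into 26 years of synthetic Sudanian months,
then mine it back:

```python
import math
import agrorules as ar
from agrorules.zones import SUDANIAN
from agrorules.rules import format_report

profile = ar.profile_from_thresholds(SUDANIAN)
records = ar.generate_monthly_records(profile, 1995, 2020, seed=40)
spec = ar.PlantedRuleSpec(
    antecedent_items=frozenset({"ET=low", "Tmin=medium", "Umax=high"}),
    consequent_item="Yield=high", target_support=0.25, target_confidence=1.0)
records = ar.plant_rule(records, spec, SUDANIAN, seed=41)
tx = ar.to_transactions(records, SUDANIAN,
                        ["Tmin", "Tmax", "Umax", "RR", "Sun", "ET", "Yield"])
min_count = math.ceil(0.2 * len(tx))
itemsets = ar.mine_fptree(ar.build_fptree([t.items for t in tx], min_count), min_count)
top = ar.rank_top_k(ar.filter_rules(ar.generate_rules(itemsets, "Yield=high", len(tx))), 5)
print(format_report("Sudanian", top))
```

prints

```
Zone: Sudanian — 1 rule(s)
  1. IF ET=low AND Tmin=medium AND Umax=high THEN Yield=high  [support=0.250, confidence=1.000, lift=2.438]
```

The planted rule is recovered with its exact support (78 of 312 months),
perfect confidence, and a lift of 2.4 — high yield is 2.4× likelier under
those three conditions than overall.

The same run is available from the shell:

```sh
agrorules simulate --out data/ --seed 5          # synthetic climate + yields
agrorules run --climate data/climate_monthly.csv --out results/ --seed 5
agrorules thresholds --out thresholds.csv        # built-in zone cutpoints
```

`agrorules run` writes, per zone, the thresholds, the basket-format
transactions, the frequent itemsets, the ranked rules and a human-readable
report, plus a `manifest.json` with SHA-256 hashes; a rerun with the same
inputs and seed is byte-identical.

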