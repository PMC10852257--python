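"""From raw climate/yield tables to per-zone transaction databases.

The pipeline stages implemented here follow standard agro-meteorological
practice for association mining:

1. daily station records are averaged into one record per (zone, year, month);
2. the annual tomato yield is disaggregated to a constant annual/12 per month
   and joined on (zone, year);
3. predictors correlating above a threshold (|Pearson r|, pooled over zones)
   are pruned, keeping one member of each offending pair;
4. per-zone cutpoints at mean +/- sd turn each attribute into a
   low/medium/high category;
5. each record becomes a transaction: a set of ``"attribute=category"`` items,
   exactly one per retained attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, EmptyInputError, JoinError,
                     MissingValueError)
from .synthetic import YIELD_COLUMN, attr_to_column, column_to_attr
from .thresholds import ThresholdTable, discretize

log = logging.getLogger(__name__)

#: the seven measured climate predictors, in the fixed keep-priority order
#: used to break ties when pruning correlated pairs (earlier wins)
PREDICTOR_PRIORITY = ("Tmin", "Tmax", "Umax", "Umin", "RR", "Sun", "ET")


@dataclass(frozen=True)
class Transaction:
    """One station-month as a set of categorical items."""

    id: tuple[str, int, int]  # (zone, year, month)
    items: frozenset[str]


def aggregate_daily_to_monthly(daily: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each attribute over the days of each (zone, year, month).

    Months with no days simply do not appear; days with a missing value for
    some attribute contribute to the other attributes' means only.
    """
    required = {"zone", "date"}
    if not required.issubset(daily.columns):
        raise ConfigurationError(
            f"daily records need columns {sorted(required)}")
    value_cols = [c for c in daily.columns if c not in ("zone", "date")]
    for col in value_cols:
        coerced = pd.to_numeric(daily[col], errors="coerce")
        bad = coerced.isna() & daily[col].notna()
        if bad.any():
            raise MissingValueError(
                f"non-numeric value in column {col!r} at rows "
                f"{list(daily.index[bad][:5])}")
    dates = pd.to_datetime(daily["date"])
    grouped = (daily.assign(year=dates.dt.year, month=dates.dt.month)
               .groupby(["zone", "year", "month"], sort=True)[value_cols]
               .mean()
               .reset_index())
    return grouped


def attach_monthly_yield(monthly: pd.DataFrame,
                         annual_yields: pd.DataFrame) -> pd.DataFrame:
    """Join yield = annual/12 onto each monthly record by (zone, year)."""
    ann = annual_yields.copy()
    ann["_monthly_yield"] = ann["annual_yield_kg_ha"] / 12.0
    merged = monthly.merge(ann[["zone", "year", "_monthly_yield"]],
                           on=["zone", "year"], how="left", validate="m:1")
    missing = merged["_monthly_yield"].isna()
    if missing.any():
        keys = sorted(set(map(tuple, merged.loc[missing, ["zone", "year"]]
                              .itertuples(index=False))))
        raise JoinError(keys)
    merged[YIELD_COLUMN] = merged.pop("_monthly_yield")
    return merged


def correlation_filter(monthly: pd.DataFrame, threshold: float = 0.8
                       ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Prune predictors with pairwise |Pearson r| above ``threshold``.

    Correlations are computed on the pooled (all-zone) monthly records.  While
    any pair exceeds the threshold, the predictor involved in the most
    offending pairs is dropped, ties going to the one later in the fixed
    priority order (so the canonical outcome of collinear humidity extremes is
    that Umin goes and Umax stays).  The response is never considered for
    dropping.  Returns (retained predictors, dropped predictors, correlation
    matrix over the original predictors).
    """
    if not 0 < threshold < 1:
        raise ConfigurationError(f"correlation threshold {threshold} not in (0,1)")
    if len(monthly) < 3:
        raise EmptyInputError("need at least 3 records for correlations")
    predictors = [p for p in PREDICTOR_PRIORITY if p in monthly.columns]
    zero_var = [p for p in predictors if monthly[p].nunique() <= 1]
    for p in zero_var:
        log.warning("attribute %s has zero variance; correlations undefined, kept", p)
    corr = monthly[predictors].corr(method="pearson")

    retained = list(predictors)
    dropped: list[str] = []
    while True:
        offending: dict[str, int] = {p: 0 for p in retained}
        any_pair = False
        for i, p in enumerate(retained):
            for q in retained[i + 1:]:
                r = corr.loc[p, q]
                if np.isfinite(r) and abs(r) > threshold:
                    offending[p] += 1
                    offending[q] += 1
                    any_pair = True
        if not any_pair:
            break
        worst = max(offending.values())
        # among the most-offending, drop the lowest-priority (latest) one
        candidates = [p for p in retained if offending[p] == worst]
        victim = max(candidates, key=PREDICTOR_PRIORITY.index)
        retained.remove(victim)
        dropped.append(victim)
    return retained, dropped, corr


def compute_thresholds(monthly: pd.DataFrame, zone: str,
                       attributes: list[str] | None = None) -> ThresholdTable:
    """Cutpoints mean - sd and mean + sd per attribute over the zone's records.

    Uses the sample (n-1) standard deviation; requires at least two records.
    """
    sub = monthly[monthly["zone"] == zone]
    if len(sub) < 2:
        raise EmptyInputError(
            f"zone {zone!r} has {len(sub)} record(s); sd undefined")
    if attributes is None:
        attributes = [column_to_attr(c) for c in sub.columns
                      if c not in ("zone", "year", "month")]
    cuts = {}
    for attr in attributes:
        col = attr_to_column(attr)
        if col not in sub.columns:
            raise ConfigurationError(f"no column for attribute {attr!r}")
        values = sub[col].astype(float)
        mean, sd = values.mean(), values.std(ddof=1)
        cuts[attr] = (mean - sd, mean + sd)
    return ThresholdTable(zone=zone, cuts=cuts)


def to_transactions(monthly: pd.DataFrame,
                    thresholds: dict[str, ThresholdTable] | ThresholdTable,
                    attributes: list[str]) -> list[Transaction]:
    """Encode each monthly record as one transaction of ``attr=category`` items.

    ``thresholds`` may be a single zone's table or a dict keyed by zone;
    ``attributes`` lists the retained attributes (the response included).
    """
    if isinstance(thresholds, ThresholdTable):
        thresholds = {thresholds.zone: thresholds}
    transactions = []
    for row in monthly.itertuples(index=False):
        zone = row.zone
        if zone not in thresholds:
            raise ConfigurationError(f"no threshold table for zone {zone!r}")
        table = thresholds[zone]
        items = []
        for attr in attributes:
            value = getattr(row, attr_to_column(attr))
            items.append(f"{attr}={discretize(float(value), table.require(attr))}")
        transactions.append(Transaction(
            id=(zone, int(row.year), int(row.month)),
            items=frozenset(items)))
    return transactions


def write_basket(transactions: list[Transaction], path: str | Path) -> None:
    """One transaction per line, items space-separated, sorted for stability."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in transactions:
            fh.write(" ".join(sorted(t.items)) + "\n")


def read_basket(path: str | Path) -> list[frozenset[str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            items = line.split()
            if items:
                out.append(frozenset(items))
    return out
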