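"""End-to-end orchestration: climate + yield CSVs in, per-zone rule tables out.

A run is fully described by a :class:`RunConfig`; rerunning the same config on
the same inputs produces byte-identical outputs (fixed CSV dialect, sorted
orders everywhere, one seed).  Each zone is mined separately with N equal to
that zone's transaction count, since thresholds — and hence item meanings —
are zone-specific.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import preprocess, rules, synthetic
from .errors import ConfigurationError
from .fpgrowth import build_fptree, mine_fptree, write_itemsets_csv
from .thresholds import (ThresholdTable, read_thresholds_csv,
                         write_thresholds_csv)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one mining run; defaults are the study's canonical ones."""

    climate_csv: str
    out_dir: str
    zones: list[str] = field(default_factory=list)
    yields_csv: str | None = None
    min_support: float = 0.2
    min_confidence: float = 0.8
    min_lift: float = 1.0
    min_antecedents: int = 3
    top_k: int = 5
    correlation_threshold: float = 0.8
    consequent_item: str = "Yield=high"
    #: "compute" derives per-zone mean +/- sd cutpoints from the data;
    #: otherwise a path to a thresholds CSV fixing the discretization grid
    thresholds: str = "compute"
    seed: int = 0

    def __post_init__(self) -> None:
        # min_support above 1 is legal and simply yields no frequent itemsets
        if self.min_support <= 0:
            raise ConfigurationError(f"min_support {self.min_support} must be > 0")
        if not 0 <= self.min_confidence <= 1:
            raise ConfigurationError(
                f"min_confidence {self.min_confidence} not in [0, 1]")
        if self.min_lift < 0:
            raise ConfigurationError(f"min_lift {self.min_lift} < 0")
        if self.min_antecedents < 1:
            raise ConfigurationError(f"min_antecedents {self.min_antecedents} < 1")
        if self.top_k < 0:
            raise ConfigurationError(f"top_k {self.top_k} < 0")
        if not 0 < self.correlation_threshold < 1:
            raise ConfigurationError(
                f"correlation_threshold {self.correlation_threshold} not in (0, 1)")


def _slug(zone: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", zone).strip("_")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate-independent stages: load, filter, discretize, mine, rank.

    Writes, per zone: a thresholds CSV, a basket-format transaction file, a
    frequent-itemset CSV and a rules CSV; plus ``manifest.json`` recording the
    config and a SHA-256 per output file.  Returns the manifest as a dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    monthly = synthetic.read_climate_csv(config.climate_csv) \
        if config.yields_csv is None else pd.read_csv(config.climate_csv)
    if config.yields_csv is not None:
        annual = synthetic.read_annual_yield_csv(config.yields_csv)
        monthly = monthly.drop(columns=[synthetic.YIELD_COLUMN], errors="ignore")
        monthly = preprocess.attach_monthly_yield(monthly, annual)

    zones = config.zones or sorted(monthly["zone"].unique())
    if not zones:
        raise ConfigurationError("no zones to process")

    retained, dropped, corr = preprocess.correlation_filter(
        monthly, config.correlation_threshold)
    attributes = retained + ["Yield"]
    corr.to_csv(out_dir / "correlation_matrix.csv", lineterminator="\n")

    given_tables: dict[str, ThresholdTable] | None = None
    if config.thresholds != "compute":
        given_tables = read_thresholds_csv(config.thresholds)

    manifest: dict = {
        "config": asdict(config),
        "dropped_attributes": dropped,
        "retained_attributes": attributes,
        "zones": {},
        "files": {},
    }
    written = [out_dir / "correlation_matrix.csv"]

    for zone in zones:
        sub = monthly[monthly["zone"] == zone]
        if len(sub) < 2:
            log.warning("zone %r has %d record(s); skipped", zone, len(sub))
            continue
        if given_tables is not None:
            if zone not in given_tables:
                raise ConfigurationError(f"no given thresholds for zone {zone!r}")
            table = given_tables[zone]
        else:
            table = preprocess.compute_thresholds(sub, zone, attributes)
        # a given grid can only discretize the attributes it covers
        zone_attrs = [a for a in attributes if a in table]
        excluded = sorted(set(attributes) - set(zone_attrs))
        if excluded:
            log.warning("zone %r: no thresholds for %s; excluded from mining",
                        zone, excluded)
        slug = _slug(zone)
        thr_path = out_dir / f"{slug}_thresholds.csv"
        write_thresholds_csv([table], thr_path)

        transactions = preprocess.to_transactions(sub, table, zone_attrs)
        basket_path = out_dir / f"{slug}_transactions.basket"
        preprocess.write_basket(transactions, basket_path)

        n = len(transactions)
        min_count = math.ceil(config.min_support * n)
        itemset_path = out_dir / f"{slug}_itemsets.csv"
        rules_path = out_dir / f"{slug}_rules.csv"
        if min_count > n:
            itemsets, top = [], []
        else:
            tree = build_fptree([t.items for t in transactions], min_count)
            itemsets = mine_fptree(tree, min_count)
            generated = rules.generate_rules(itemsets, config.consequent_item, n)
            kept = rules.filter_rules(generated, config.min_confidence,
                                      config.min_lift, config.min_antecedents)
            top = rules.rank_top_k(kept, config.top_k)
        write_itemsets_csv(itemsets, itemset_path)
        rules.write_rules_csv(top, rules_path)
        report_path = out_dir / f"{slug}_report.txt"
        report_path.write_text(rules.format_report(zone, top), encoding="utf-8")

        manifest["zones"][zone] = {
            "n_transactions": n,
            "min_support_count": min_count,
            "n_frequent_itemsets": len(itemsets),
            "n_rules_reported": len(top),
        }
        written += [thr_path, basket_path, itemset_path, rules_path, report_path]

    for path in written:
        manifest["files"][path.name] = _sha256(path)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest
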