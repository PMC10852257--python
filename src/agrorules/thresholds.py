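"""Per-zone three-level discretization thresholds.

Each climate attribute (and the yield) is categorised per agro-ecological zone
as ``low`` / ``medium`` / ``high`` using two cutpoints derived from the zone's
mean and standard deviation: values at or below ``mean - sd`` are *low*, values
at or above ``mean + sd`` are *high*, and the open interval between the
cutpoints is *medium*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, InvalidTableError, MissingValueError

#: canonical attribute order used everywhere (predictors then response)
ATTRIBUTES = ("Tmin", "Tmax", "Umin", "Umax", "RR", "Sun", "ET", "Yield")

CATEGORIES = ("low", "medium", "high")


@dataclass(frozen=True)
class ThresholdTable:
    """Two cutpoints per attribute for one zone.

    ``cuts`` maps an attribute name to ``(low_cut, high_cut)`` with
    ``low_cut <= high_cut``.  A value ``v`` is *low* iff ``v <= low_cut`` and
    *high* iff ``v >= high_cut``; the medium band is open on both sides.
    """

    zone: str
    cuts: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr, (lo, hi) in self.cuts.items():
            if lo > hi:
                raise InvalidTableError(
                    f"{self.zone}/{attr}: low_cut {lo} > high_cut {hi}"
                )

    def __contains__(self, attr: str) -> bool:
        return attr in self.cuts

    def require(self, attr: str) -> tuple[float, float]:
        try:
            return self.cuts[attr]
        except KeyError:
            raise ConfigurationError(
                f"threshold table for zone {self.zone!r} has no attribute {attr!r}"
            ) from None


def discretize(value: float, cutpoints: tuple[float, float]) -> str:
    """Classify ``value`` as ``low``/``medium``/``high`` given ``(low_cut, high_cut)``.

    Cutpoints belong to the extreme categories; the medium interval is open on
    both sides.  In the degenerate case ``low_cut == high_cut`` the ``<=`` test
    runs first, so the shared cutpoint classifies as ``low``.
    """
    low_cut, high_cut = cutpoints
    if low_cut > high_cut:
        raise InvalidTableError(f"low_cut {low_cut} > high_cut {high_cut}")
    if isinstance(value, float) and math.isnan(value):
        raise MissingValueError("cannot discretize NaN")
    if value <= low_cut:
        return "low"
    if value >= high_cut:
        return "high"
    return "medium"


def write_thresholds_csv(tables: list[ThresholdTable], path: str | Path) -> None:
    """Write tables as CSV with one row per (zone, attribute).

    Layout mirrors the published per-zone threshold tables: the two cutpoints
    define the ``<= low_cut`` / ``]low_cut; high_cut[`` / ``>= high_cut`` bands.
    """
    rows = []
    for table in tables:
        for attr, (lo, hi) in table.cuts.items():
            rows.append({"zone": table.zone, "attribute": attr,
                         "low_cut": lo, "high_cut": hi})
    df = pd.DataFrame(rows, columns=["zone", "attribute", "low_cut", "high_cut"])
    df.to_csv(path, index=False, lineterminator="\n")


def read_thresholds_csv(path: str | Path) -> dict[str, ThresholdTable]:
    """Inverse of :func:`write_thresholds_csv`; returns tables keyed by zone."""
    df = pd.read_csv(path)
    required = {"zone", "attribute", "low_cut", "high_cut"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"thresholds CSV {path} missing columns {sorted(required - set(df.columns))}"
        )
    tables: dict[str, ThresholdTable] = {}
    for zone, grp in df.groupby("zone", sort=False):
        cuts = {
            str(r.attribute): (float(r.low_cut), float(r.high_cut))
            for r in grp.itertuples()
        }
        tables[str(zone)] = ThresholdTable(zone=str(zone), cuts=cuts)
    return tables
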