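"""Zone-structured synthetic climate/yield data with known statistical structure.

Real station records behind the published per-zone thresholds are not publicly
deposited, so every downstream stage (aggregation, correlation filter,
discretization, mining) is exercised on data generated here.  Each attribute is
drawn independently from a normal distribution truncated at its physical range
(rainfall, sunshine, evapotranspiration and yield are non-negative; humidities
live in [0, 100]; temperatures are unbounded), with the mean and standard
deviation taken from a :class:`ZoneClimateProfile` — typically reconstructed
from a published threshold table by inverting the mean +/- sd construction.

Two deliberate dependence mechanisms exist on top of the independent draws:

* minimum humidity can be generated as ``0.9 * Umax + noise`` so that the
  correlation-filter stage has a >0.8 pair to drop, emulating the collinearity
  observed between the humidity extremes at the real stations;
* :func:`plant_rule` rewrites a controlled subset of records so that, after
  discretization, a chosen antecedent -> consequent association holds with an
  exact support count and a confidence as close to the target as the integer
  grid allows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InfeasibleRuleError, InvalidTableError
from .thresholds import ThresholdTable

#: physical truncation bounds per attribute
PHYSICAL_BOUNDS: dict[str, tuple[float, float]] = {
    "Tmin": (-np.inf, np.inf),
    "Tmax": (-np.inf, np.inf),
    "Umin": (0.0, 100.0),
    "Umax": (0.0, 100.0),
    "RR": (0.0, np.inf),
    "Sun": (0.0, np.inf),
    "ET": (0.0, np.inf),
    "Yield": (0.0, np.inf),
}

#: DataFrame column holding the yield attribute
YIELD_COLUMN = "yield_kg_ha"

CLIMATE_COLUMNS = ["zone", "year", "month",
                   "Tmin", "Tmax", "Umin", "Umax", "RR", "Sun", "ET",
                   YIELD_COLUMN]


def attr_to_column(attr: str) -> str:
    return YIELD_COLUMN if attr == "Yield" else attr


def column_to_attr(col: str) -> str:
    return "Yield" if col == YIELD_COLUMN else col


@dataclass(frozen=True)
class ZoneClimateProfile:
    """Per-zone mean and standard deviation for every generated attribute."""

    zone_name: str
    params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr, (_, sd) in self.params.items():
            if sd < 0:
                raise ConfigurationError(f"{self.zone_name}/{attr}: sd {sd} < 0")

    def mean(self, attr: str) -> float:
        return self.params[attr][0]

    def sd(self, attr: str) -> float:
        return self.params[attr][1]


@dataclass(frozen=True)
class PlantedRuleSpec:
    """A deliberately injected association with known support and confidence.

    Items are ``"attribute=category"`` strings; the consequent is a single item
    disjoint from the antecedents.  Feasibility requires
    ``target_support <= target_confidence`` (the planted itemset cannot occur
    more often than the antecedent alone).
    """

    antecedent_items: frozenset[str]
    consequent_item: str
    target_support: float
    target_confidence: float

    def __post_init__(self) -> None:
        if not self.antecedent_items:
            raise ConfigurationError("antecedent_items must be nonempty")
        if self.consequent_item in self.antecedent_items:
            raise ConfigurationError("consequent must not appear in antecedents")
        if not (0 < self.target_support <= 1):
            raise ConfigurationError("target_support must be in (0, 1]")
        if not (0 < self.target_confidence <= 1):
            raise ConfigurationError("target_confidence must be in (0, 1]")
        if self.target_support > self.target_confidence:
            raise InfeasibleRuleError(
                "target_support > target_confidence is unachievable"
            )


def parse_item(item: str) -> tuple[str, str]:
    attr, _, cat = item.partition("=")
    if not cat:
        raise ConfigurationError(f"malformed item {item!r}; expected 'attr=category'")
    return attr, cat


# ---------------------------------------------------------------------------
# profile <-> threshold-table round trip

def profile_from_thresholds(table: ThresholdTable) -> ZoneClimateProfile:
    """Invert the mean +/- sd construction: midpoint and half-width per attribute."""
    params = {}
    for attr, (lo, hi) in table.cuts.items():
        if lo > hi:
            raise InvalidTableError(f"{table.zone}/{attr}: low_cut > high_cut")
        params[attr] = ((lo + hi) / 2.0, (hi - lo) / 2.0)
    return ZoneClimateProfile(zone_name=table.zone, params=params)


def thresholds_from_profile(profile: ZoneClimateProfile) -> ThresholdTable:
    cuts = {attr: (m - s, m + s) for attr, (m, s) in profile.params.items()}
    return ThresholdTable(zone=profile.zone_name, cuts=cuts)


# ---------------------------------------------------------------------------
# sampling

def _draw_truncated(mean: float, sd: float, bounds: tuple[float, float],
                    size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    lo, hi = bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def truncated_moments(profile: ZoneClimateProfile, attr: str) -> tuple[float, float]:
    """Theoretical mean and sd of the truncated sampling distribution.

    For attributes whose nominal mean sits close to a physical bound (in units
    of sd), truncation shifts the realised moments away from the nominal
    profile values; recovery tests compare against these, the distribution the
    data actually came from.
    """
    mean, sd = profile.params[attr]
    if sd == 0:
        return mean, 0.0
    lo, hi = PHYSICAL_BOUNDS.get(attr, (-np.inf, np.inf))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    m, v = stats.truncnorm.stats(a, b, loc=mean, scale=sd, moments="mv")
    return float(m), float(math.sqrt(v))


def generate_monthly_records(profile: ZoneClimateProfile, start_year: int,
                             end_year: int, seed: int | np.random.SeedSequence,
                             umin_from_umax: bool = True) -> pd.DataFrame:
    """One record per (zone, year, month); 12 x (span of years) rows.

    With ``umin_from_umax`` (default) minimum humidity is ``0.9 * Umax`` plus
    N(0, 2) noise clipped to [0, 100], giving the >0.8 correlation the filter
    stage is meant to detect; otherwise Umin needs its own profile entry.
    """
    if start_year > end_year:
        raise ConfigurationError(f"start_year {start_year} > end_year {end_year}")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)
    n = 12 * len(years)
    data: dict[str, np.ndarray] = {
        "year": np.repeat(years, 12),
        "month": np.tile(np.arange(1, 13), len(years)),
    }
    for attr in ("Tmin", "Tmax", "Umax", "RR", "Sun", "ET", "Yield"):
        if attr not in profile.params:
            raise ConfigurationError(
                f"profile {profile.zone_name!r} lacks attribute {attr!r}"
            )
        mean, sd = profile.params[attr]
        data[attr_to_column(attr)] = _draw_truncated(
            mean, sd, PHYSICAL_BOUNDS[attr], n, rng)
    if umin_from_umax:
        noise = rng.normal(0.0, 2.0, size=n)
        data["Umin"] = np.clip(0.9 * data["Umax"] + noise, 0.0, 100.0)
    else:
        if "Umin" not in profile.params:
            raise ConfigurationError(
                f"profile {profile.zone_name!r} lacks attribute 'Umin'"
            )
        mean, sd = profile.params["Umin"]
        data["Umin"] = _draw_truncated(mean, sd, PHYSICAL_BOUNDS["Umin"], n, rng)
    df = pd.DataFrame(data)
    df.insert(0, "zone", profile.zone_name)
    return df[CLIMATE_COLUMNS]


#: day-to-day noise scale as a fraction of the monthly-mean sd; nuisance
#: variation that monthly averaging removes (contributes ~sd/sqrt(30) extra)
DAILY_NOISE_FRACTION = 0.5


def generate_daily_records(profile: ZoneClimateProfile, start_year: int,
                           end_year: int, seed: int | np.random.SeedSequence,
                           umin_from_umax: bool = True) -> pd.DataFrame:
    """Daily station records for exercising the monthly-aggregation path.

    The profile describes *monthly-mean* variability (the discretization
    thresholds are defined on monthly data), so each month first receives a
    latent monthly mean drawn from the profile's truncated normal and every
    day of that month is the latent mean plus day-level noise of scale
    ``DAILY_NOISE_FRACTION * sd``, re-truncated to the physical range.
    Monthly averages therefore recover the profile's mean and (nearly) its sd.
    Columns: ``zone, date`` plus the seven climate attributes (yield arrives
    later via the annual-yield join).
    """
    if start_year > end_year:
        raise ConfigurationError(f"start_year {start_year} > end_year {end_year}")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    n = len(dates)
    n_months = 12 * (end_year - start_year + 1)
    # index of each date's month within the span
    month_idx = (dates.year - start_year) * 12 + (dates.month - 1)
    data: dict[str, np.ndarray] = {}
    for attr in ("Tmin", "Tmax", "Umax", "RR", "Sun", "ET"):
        mean, sd = profile.params[attr]
        bounds = PHYSICAL_BOUNDS[attr]
        latent = _draw_truncated(mean, sd, bounds, n_months, rng)
        centers = latent[month_idx]
        if sd == 0:
            data[attr] = centers
            continue
        daily_sd = DAILY_NOISE_FRACTION * sd
        lo, hi = bounds
        a = (lo - centers) / daily_sd
        b = (hi - centers) / daily_sd
        data[attr] = stats.truncnorm.rvs(a, b, loc=centers, scale=daily_sd,
                                         size=n, random_state=rng)
    if umin_from_umax:
        noise = rng.normal(0.0, 2.0, size=n)
        data["Umin"] = np.clip(0.9 * data["Umax"] + noise, 0.0, 100.0)
    else:
        mean, sd = profile.params["Umin"]
        data["Umin"] = _draw_truncated(mean, sd, PHYSICAL_BOUNDS["Umin"], n, rng)
    df = pd.DataFrame(data)
    df.insert(0, "date", dates)
    df.insert(0, "zone", profile.zone_name)
    return df[["zone", "date", "Tmin", "Tmax", "Umin", "Umax", "RR", "Sun", "ET"]]


def annual_yields_from_monthly(monthly: pd.DataFrame) -> pd.DataFrame:
    """Annual yield per (zone, year) as 12 x the mean monthly yield.

    Provides the companion table for the disaggregation path, which spreads the
    annual figure back as a constant annual/12 per month.
    """
    grp = monthly.groupby(["zone", "year"], sort=True)[YIELD_COLUMN].mean()
    out = (12.0 * grp).reset_index()
    out.columns = ["zone", "year", "annual_yield_kg_ha"]
    return out


def generate_annual_yields(profiles: list[ZoneClimateProfile], start_year: int,
                           end_year: int, seed: int) -> pd.DataFrame:
    """Annual yield per (zone, year): 12 x a draw from the monthly-yield profile.

    Companion to :func:`generate_daily_dataset`, whose records carry no yield;
    the disaggregation step later spreads each annual figure as annual/12.
    """
    frames = []
    for i, profile in enumerate(profiles):
        # distinct spawn key so yields never share a stream with climate draws
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7, i)))
        years = np.arange(start_year, end_year + 1)
        mean, sd = profile.params["Yield"]
        monthly = _draw_truncated(mean, sd, PHYSICAL_BOUNDS["Yield"],
                                  len(years), rng)
        frames.append(pd.DataFrame({
            "zone": profile.zone_name,
            "year": years,
            "annual_yield_kg_ha": 12.0 * monthly,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_dataset(profiles: list[ZoneClimateProfile], start_year: int,
                     end_year: int, seed: int,
                     umin_from_umax: bool = True) -> pd.DataFrame:
    """Monthly records for several zones from one master seed.

    Per-zone substreams are spawned deterministically from the master seed, so
    adding or reordering zones never perturbs another zone's draws.
    """
    children = np.random.SeedSequence(seed).spawn(len(profiles))
    frames = [
        generate_monthly_records(p, start_year, end_year, child,
                                 umin_from_umax=umin_from_umax)
        for p, child in zip(profiles, children)
    ]
    return pd.concat(frames, ignore_index=True)


def generate_daily_dataset(profiles: list[ZoneClimateProfile], start_year: int,
                           end_year: int, seed: int,
                           umin_from_umax: bool = True) -> pd.DataFrame:
    children = np.random.SeedSequence(seed).spawn(len(profiles))
    frames = [
        generate_daily_records(p, start_year, end_year, child,
                               umin_from_umax=umin_from_umax)
        for p, child in zip(profiles, children)
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# rule planting

def _sample_in_band(attr: str, category: str, table: ThresholdTable,
                    rng: np.random.Generator) -> float:
    """Draw a value that discretizes to ``category`` under ``table``."""
    lo, hi = table.require(attr)
    phys_lo, phys_hi = PHYSICAL_BOUNDS.get(attr, (-np.inf, np.inf))
    sd = (hi - lo) / 2.0 or 1.0
    if category == "low":
        floor = max(lo - sd, phys_lo)
        if floor > lo:
            raise InfeasibleRuleError(f"{attr}=low band empty under physical bounds")
        return rng.uniform(floor, lo)
    if category == "high":
        ceil_ = min(hi + sd, phys_hi)
        if ceil_ < hi:
            raise InfeasibleRuleError(f"{attr}=high band empty under physical bounds")
        return rng.uniform(hi, ceil_)
    if category == "medium":
        if not lo < hi:
            raise InfeasibleRuleError(f"{attr}=medium band empty (degenerate cuts)")
        margin = 0.05 * (hi - lo)
        return rng.uniform(lo + margin, hi - margin)
    raise ConfigurationError(f"unknown category {category!r}")


def _other_category(attr: str, category: str, table: ThresholdTable) -> str:
    lo, hi = table.require(attr)
    for cat in ("low", "high", "medium"):
        if cat == category:
            continue
        if cat == "medium" and not lo < hi:
            continue
        return cat
    raise InfeasibleRuleError(f"no alternative category for {attr}")


def plant_rule(records: pd.DataFrame, spec: PlantedRuleSpec,
               table: ThresholdTable, seed: int) -> pd.DataFrame:
    """Rewrite records so the planted association holds exactly after discretization.

    Let ``n`` be the record count and ``k = ceil(target_support * n)``.  The
    full itemset (antecedents plus consequent) is written into exactly ``k``
    records; the antecedent alone into ``m - k`` further records, where ``m``
    is the integer in ``[k, n]`` whose ratio ``k / m`` is closest to the target
    confidence; and in every remaining record the first antecedent attribute is
    forced *out* of its planted category, so no accidental occurrence of the
    full antecedent survives.  Raises :class:`InfeasibleRuleError` when no
    ``m`` brings the confidence within ``1/n`` of the target.
    """
    n = len(records)
    if n == 0:
        raise ConfigurationError("no records to plant into")
    antecedents = sorted(parse_item(i) for i in spec.antecedent_items)
    consequent = parse_item(spec.consequent_item)
    for attr, _ in antecedents + [consequent]:
        table.require(attr)

    k = math.ceil(spec.target_support * n)
    # best achievable antecedent count for the confidence target
    candidates = [m for m in
                  {math.floor(k / spec.target_confidence),
                   math.ceil(k / spec.target_confidence)}
                  if k <= m <= n]
    if not candidates:
        raise InfeasibleRuleError(
            f"no antecedent count in [{k}, {n}] for confidence "
            f"{spec.target_confidence}")
    m = min(candidates, key=lambda m: abs(k / m - spec.target_confidence))
    if abs(k / m - spec.target_confidence) > 1.0 / n:
        raise InfeasibleRuleError(
            f"closest achievable confidence {k}/{m} is farther than 1/n "
            f"from target {spec.target_confidence}")

    rng = np.random.default_rng(seed)
    out = records.reset_index(drop=True).copy()
    chosen = rng.choice(n, size=m, replace=False)
    full_idx, ant_only_idx = chosen[:k], chosen[k:]
    rest = np.setdiff1d(np.arange(n), chosen)

    for attr, cat in antecedents:
        col = attr_to_column(attr)
        out.loc[full_idx, col] = [_sample_in_band(attr, cat, table, rng)
                                  for _ in range(len(full_idx))]
        out.loc[ant_only_idx, col] = [_sample_in_band(attr, cat, table, rng)
                                      for _ in range(len(ant_only_idx))]
    c_attr, c_cat = consequent
    c_col = attr_to_column(c_attr)
    out.loc[full_idx, c_col] = [_sample_in_band(c_attr, c_cat, table, rng)
                                for _ in range(k)]
    if len(ant_only_idx):
        alt = _other_category(c_attr, c_cat, table)
        out.loc[ant_only_idx, c_col] = [_sample_in_band(c_attr, alt, table, rng)
                                        for _ in range(len(ant_only_idx))]
    # break the antecedent everywhere else so its count is exactly m
    b_attr, b_cat = antecedents[0]
    b_col = attr_to_column(b_attr)
    alt = _other_category(b_attr, b_cat, table)
    out.loc[rest, b_col] = [_sample_in_band(b_attr, alt, table, rng)
                            for _ in range(len(rest))]
    return out


# ---------------------------------------------------------------------------
# CSV output

def write_climate_csv(df: pd.DataFrame, path: str | Path) -> None:
    """UTF-8, dot-decimal, LF-terminated CSV; byte-identical for equal inputs."""
    df.to_csv(path, index=False, lineterminator="\n")


def write_annual_yield_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def read_climate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"climate CSV {path} missing columns {sorted(missing)}")
    return df


def read_annual_yield_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"zone", "year", "annual_yield_kg_ha"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"annual-yield CSV {path} missing columns {sorted(missing)}")
    return df
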