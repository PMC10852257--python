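"""Aggregation, yield disaggregation, correlation filter, threshold fitting."""

import math

import numpy as np
import pandas as pd
import pytest

from agrorules import (aggregate_daily_to_monthly, attach_monthly_yield,
                       compute_thresholds, correlation_filter,
                       to_transactions)
from agrorules.errors import (ConfigurationError, EmptyInputError, JoinError,
                              MissingValueError)
from agrorules.synthetic import (generate_daily_dataset,
                                 generate_monthly_records, truncated_moments)
from agrorules.zones import SUDANIAN


def _daily_frame(values_by_day, zone="Z", year=2000, month=1, attr="ET"):
    days = pd.date_range(f"{year}-{month:02d}-01", periods=len(values_by_day))
    return pd.DataFrame({"zone": zone, "date": days, attr: values_by_day})


class TestAggregation:
    def test_three_zones_26_years_gives_936(self, all_profiles):
        daily = generate_daily_dataset(all_profiles, 1995, 2020, 2)
        monthly = aggregate_daily_to_monthly(daily)
        assert len(monthly) == 936
        assert monthly.groupby("zone").size().eq(312).all()

    def test_single_day_month_is_identity(self):
        monthly = aggregate_daily_to_monthly(_daily_frame([4.2]))
        assert monthly["ET"].tolist() == [4.2]

    def test_constructed_month_mean(self):
        monthly = aggregate_daily_to_monthly(_daily_frame(list(range(1, 31))))
        assert monthly["ET"].iloc[0] == pytest.approx(15.5)

    def test_aggregating_monthly_data_is_idempotent(self, sudanian_profile):
        m = generate_monthly_records(sudanian_profile, 2000, 2001, 5)
        as_daily = m.assign(
            date=pd.to_datetime(dict(year=m.year, month=m.month, day=1))
        ).drop(columns=["year", "month"])
        again = aggregate_daily_to_monthly(as_daily)
        for col in ("Tmin", "ET", "yield_kg_ha"):
            np.testing.assert_allclose(again[col], m[col])

    def test_non_numeric_value_raises_with_row(self):
        frame = _daily_frame([1.0, "oops", 3.0])
        with pytest.raises(MissingValueError, match="ET"):
            aggregate_daily_to_monthly(frame)

    def test_missing_days_use_available_days_only(self):
        frame = _daily_frame([1.0, np.nan, 3.0])
        monthly = aggregate_daily_to_monthly(frame)
        assert monthly["ET"].iloc[0] == pytest.approx(2.0)


class TestYieldAttachment:
    def _monthly(self):
        return pd.DataFrame({"zone": "Z", "year": 2000,
                             "month": range(1, 13), "ET": 1.0})

    def test_annual_divided_by_twelve(self):
        ann = pd.DataFrame({"zone": ["Z"], "year": [2000],
                            "annual_yield_kg_ha": [1200.0]})
        out = attach_monthly_yield(self._monthly(), ann)
        assert (out["yield_kg_ha"] == 100.0).all()

    def test_zero_annual_yield(self):
        ann = pd.DataFrame({"zone": ["Z"], "year": [2000],
                            "annual_yield_kg_ha": [0.0]})
        out = attach_monthly_yield(self._monthly(), ann)
        assert (out["yield_kg_ha"] == 0.0).all()

    def test_sum_over_year_conserves_annual(self):
        ann = pd.DataFrame({"zone": ["Z"], "year": [2000],
                            "annual_yield_kg_ha": [987.6]})
        out = attach_monthly_yield(self._monthly(), ann)
        assert out["yield_kg_ha"].sum() == pytest.approx(987.6)

    def test_missing_key_lists_it(self):
        ann = pd.DataFrame({"zone": ["Other"], "year": [2000],
                            "annual_yield_kg_ha": [1.0]})
        with pytest.raises(JoinError) as err:
            attach_monthly_yield(self._monthly(), ann)
        assert ("Z", 2000) in err.value.missing_keys


class TestCorrelationFilter:
    def test_collinear_umin_dropped(self, all_profiles):
        daily = generate_daily_dataset(all_profiles, 1995, 2020, 1)
        monthly = aggregate_daily_to_monthly(daily)
        retained, dropped, corr = correlation_filter(monthly, 0.8)
        assert dropped == ["Umin"]
        assert len(retained) == 6
        assert abs(corr.loc["Umin", "Umax"]) > 0.8

    def test_independent_predictors_nothing_dropped(self):
        rng = np.random.default_rng(0)
        monthly = pd.DataFrame(
            rng.normal(size=(500, 4)), columns=["Tmin", "Tmax", "RR", "Sun"])
        monthly["zone"] = "Z"
        retained, dropped, _ = correlation_filter(monthly, 0.8)
        assert dropped == []
        assert retained == ["Tmin", "Tmax", "RR", "Sun"]

    def test_duplicate_column_one_of_pair_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        monthly = pd.DataFrame({"zone": "Z", "Tmax": x, "Umax": x,
                                "RR": rng.normal(size=100)})
        retained, dropped, _ = correlation_filter(monthly, 0.8)
        # tie on pair counts: the lower-priority member (Umax) goes
        assert dropped == ["Umax"]
        assert "Tmax" in retained

    def test_zero_variance_attribute_kept_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        monthly = pd.DataFrame({"zone": "Z", "Tmax": 5.0,
                                "RR": rng.normal(size=50),
                                "Sun": rng.normal(size=50)})
        with caplog.at_level("WARNING"):
            retained, dropped, _ = correlation_filter(monthly, 0.8)
        assert "Tmax" in retained and dropped == []
        assert any("zero variance" in r.message for r in caplog.records)

    def test_threshold_range_enforced(self):
        monthly = pd.DataFrame({"zone": "Z", "RR": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigurationError):
            correlation_filter(monthly, 1.5)


class TestComputeThresholds:
    def test_hand_arithmetic_1_2_3(self):
        monthly = pd.DataFrame({"zone": "Z", "year": 2000, "month": [1, 2, 3],
                                "ET": [1.0, 2.0, 3.0]})
        table = compute_thresholds(monthly, "Z", ["ET"])
        assert table.cuts["ET"] == pytest.approx((1.0, 3.0))  # sd uses n-1

    def test_constant_attribute_degenerate_cuts(self):
        monthly = pd.DataFrame({"zone": "Z", "year": 2000, "month": [1, 2],
                                "ET": [2.0, 2.0]})
        table = compute_thresholds(monthly, "Z", ["ET"])
        assert table.cuts["ET"] == pytest.approx((2.0, 2.0))

    def test_single_record_rejected(self):
        monthly = pd.DataFrame({"zone": "Z", "year": [2000], "month": [1],
                                "ET": [2.0]})
        with pytest.raises(EmptyInputError):
            compute_thresholds(monthly, "Z", ["ET"])

    def test_recovers_generator_cutpoints_within_three_se(self, sudanian_profile):
        df = generate_monthly_records(sudanian_profile, 1995, 2020, 1234)
        table = compute_thresholds(df, "Sudanian", list(sudanian_profile.params))
        n = len(df)
        for attr in sudanian_profile.params:
            m_t, s_t = truncated_moments(sudanian_profile, attr)
            se = s_t * math.sqrt(1 / n + 1 / (2 * (n - 1)))
            lo, hi = table.cuts[attr]
            assert abs(lo - (m_t - s_t)) < 3 * se, attr
            assert abs(hi - (m_t + s_t)) < 3 * se, attr


class TestTransactions:
    ATTRS = ["Tmin", "Tmax", "Umax", "RR", "Sun", "ET", "Yield"]

    def test_one_transaction_per_record_seven_items(self, sudanian_profile):
        df = generate_monthly_records(sudanian_profile, 1995, 2020, 6)
        tx = to_transactions(df, SUDANIAN, self.ATTRS)
        assert len(tx) == 312
        assert all(len(t.items) == 7 for t in tx)
        # exactly one item per attribute
        for t in tx:
            attrs = [i.split("=")[0] for i in t.items]
            assert sorted(attrs) == sorted(self.ATTRS)

    def test_all_medium_record(self):
        row = pd.DataFrame({"zone": "Sudanian", "year": 2000, "month": [1],
                            "Tmin": 22.0, "Tmax": 34.0, "Umax": 70.0,
                            "RR": 0.2, "Sun": 8.0, "ET": 4.0,
                            "yield_kg_ha": 400.0})
        (t,) = to_transactions(row, SUDANIAN, self.ATTRS)
        assert all(i.endswith("=medium") for i in t.items)

    def test_item_frequencies_match_column_tabulation(self, sudanian_profile):
        from agrorules.thresholds import discretize
        from agrorules.synthetic import attr_to_column
        df = generate_monthly_records(sudanian_profile, 1995, 2020, 6)
        tx = to_transactions(df, SUDANIAN, self.ATTRS)
        for attr in self.ATTRS:
            cats = df[attr_to_column(attr)].map(
                lambda v: discretize(v, SUDANIAN.cuts[attr]))
            for cat, count in cats.value_counts().items():
                mined = sum(1 for t in tx if f"{attr}={cat}" in t.items)
                assert mined == count

    def test_missing_zone_table_rejected(self, sudanian_profile):
        df = generate_monthly_records(sudanian_profile, 2000, 2000, 6)
        df["zone"] = "Atacora"
        with pytest.raises(ConfigurationError):
            to_transactions(df, SUDANIAN, self.ATTRS)

    def test_basket_round_trip(self, sudanian_profile, tmp_path):
        from agrorules.preprocess import read_basket, write_basket
        df = generate_monthly_records(sudanian_profile, 2000, 2001, 6)
        tx = to_transactions(df, SUDANIAN, self.ATTRS)
        path = tmp_path / "tx.basket"
        write_basket(tx, path)
        assert read_basket(path) == [t.items for t in tx]
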