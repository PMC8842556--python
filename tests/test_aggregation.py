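"""Aggregation rules, Tukey-fence winsorisation, distribution summaries, ranks."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rhcp
from rhcp.aggregation import MissingFieldError


def quantile_oracle(values, q):
    """Independent sort-and-interpolate quantile (linear between order stats)."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo, hi = math.floor(h), math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def make_defn(kind, **overrides):
    rec = {
        "indicator_id": "toy",
        "label": "Toy",
        "domain": "D1",
        "aggregation_kind": kind,
        "numerator_field": "num",
    }
    if kind == "ratio_of_sums":
        rec["denominator_field"] = "den"
    if kind == "nearest_facility_time":
        rec.pop("numerator_field")
        rec["facility_type"] = "hospital"
    rec.update(overrides)
    return rhcp.IndicatorDefinition(**rec)


def raw_table(**fields):
    """Long table from field -> {municipality: value}."""
    rows = [
        (mid, fname, v)
        for fname, series in fields.items()
        for mid, v in series.items()
    ]
    return pd.DataFrame(rows, columns=["municipality_id", "field_name", "value"])


@pytest.fixture()
def trivial_net():
    g = nx.Graph()
    g.add_nodes_from(["A", "B", "C"])
    return g


class TestAggregateOverRegion:
    def test_mean_of_member_values(self, trivial_net, empty_facilities):
        defn = make_defn("mean")
        raw = raw_table(num={"A": 10.0, "B": 20.0})
        value, _, _ = rhcp.aggregate_over_region(defn, ["A", "B"], raw, empty_facilities, trivial_net)
        assert value == 15.0

    def test_sum_of_member_values(self, trivial_net, empty_facilities):
        defn = make_defn("sum")
        raw = raw_table(num={"A": 1.0, "B": 0.0, "C": 2.0})
        value, abs_num, abs_den = rhcp.aggregate_over_region(
            defn, ["A", "B", "C"], raw, empty_facilities, trivial_net
        )
        assert value == 3.0 and abs_num == 3.0 and abs_den is None

    def test_ratio_of_sums_from_regional_totals(self, trivial_net, empty_facilities):
        # hand oracle: (500 + 300) / (1 + 0) = 800
        defn = make_defn("ratio_of_sums")
        raw = raw_table(num={"A": 500.0, "B": 300.0}, den={"A": 1.0, "B": 0.0})
        value, abs_num, abs_den = rhcp.aggregate_over_region(
            defn, ["A", "B"], raw, empty_facilities, trivial_net
        )
        assert value == 800.0 and abs_num == 800.0 and abs_den == 1.0

    def test_ratio_zero_denominator_gives_missing(self, trivial_net, empty_facilities):
        defn = make_defn("ratio_of_sums")
        raw = raw_table(num={"A": 5.0}, den={"A": 0.0})
        value, _, _ = rhcp.aggregate_over_region(defn, ["A"], raw, empty_facilities, trivial_net)
        assert math.isnan(value)

    def test_ratio_scale_per_applied(self, trivial_net, empty_facilities):
        defn = make_defn("ratio_of_sums", scale_per=100000)
        raw = raw_table(num={"A": 2.0}, den={"A": 50000.0})
        value, _, _ = rhcp.aggregate_over_region(defn, ["A"], raw, empty_facilities, trivial_net)
        assert value == 4.0

    def test_singleton_ratio_equals_own_ratio(self, trivial_net, empty_facilities):
        defn = make_defn("ratio_of_sums")
        raw = raw_table(num={"A": 7.0}, den={"A": 2.0})
        value, _, _ = rhcp.aggregate_over_region(defn, ["A"], raw, empty_facilities, trivial_net)
        assert value == 3.5

    def test_nearest_facility_time_from_location(self, line_network):
        fac = pd.DataFrame(
            [("F1", "hospital", "C")], columns=["facility_id", "facility_type", "municipality_id"]
        )
        defn = make_defn("nearest_facility_time")
        raw = raw_table(num={"A": 0.0, "B": 0.0, "C": 0.0})
        value, _, _ = rhcp.aggregate_over_region(
            defn, ["A", "B"], raw, fac, line_network, location="A"
        )
        assert value == 9.0

    def test_empty_member_set_rejected(self, trivial_net, empty_facilities):
        defn = make_defn("mean")
        raw = raw_table(num={"A": 1.0})
        with pytest.raises(ValueError):
            rhcp.aggregate_over_region(defn, [], raw, empty_facilities, trivial_net)

    def test_missing_field_error_names_field_and_municipality(self, trivial_net, empty_facilities):
        defn = make_defn("mean", numerator_field="ghost")
        raw = raw_table(num={"A": 1.0})
        with pytest.raises(MissingFieldError, match="ghost"):
            rhcp.aggregate_over_region(defn, ["A"], raw, empty_facilities, trivial_net)
        raw2 = raw_table(num={"A": 1.0, "B": float("nan")})
        with pytest.raises(MissingFieldError, match="'B'"):
            rhcp.aggregate_over_region(make_defn("mean"), ["A", "B"], raw2, empty_facilities, trivial_net)

    def test_row_order_invariance(self, trivial_net, empty_facilities):
        defn = make_defn("mean")
        raw = raw_table(num={"A": 1.0, "B": 2.0, "C": 7.0})
        shuffled = raw.sample(frac=1, random_state=0)
        v1, _, _ = rhcp.aggregate_over_region(defn, ["A", "B", "C"], raw, empty_facilities, trivial_net)
        v2, _, _ = rhcp.aggregate_over_region(defn, ["C", "A", "B"], shuffled, empty_facilities, trivial_net)
        assert v1 == v2

    def test_population_weighted_mean_switch(self, trivial_net, empty_facilities):
        defn = make_defn("mean")
        raw = raw_table(num={"A": 10.0, "B": 20.0}, pop_total={"A": 1.0, "B": 3.0})
        value, _, _ = rhcp.aggregate_over_region(
            defn, ["A", "B"], raw, empty_facilities, trivial_net, population_weighted=True
        )
        assert value == pytest.approx(17.5)


class TestCleanOutliers:
    def test_constant_values_unchanged(self):
        values = {f"D{i}": 4.2 for i in range(10)}
        cleaned, flags = rhcp.clean_outliers(values)
        assert cleaned == values and flags == []

    def test_high_outlier_winsorised_to_upper_fence(self):
        # sorted {1,2,3,4,100}: Q1=2, Q3=4, IQR=2 -> upper fence 4 + 3*2 = 10
        values = dict(zip("abcde", [1.0, 2.0, 3.0, 4.0, 100.0]))
        cleaned, flags = rhcp.clean_outliers(values)
        assert cleaned["e"] == 10.0 and flags == ["e"]
        assert all(cleaned[k] == values[k] for k in "abcd")

    def test_low_outlier_winsorised_to_lower_fence(self):
        values = dict(zip("abcde", [-100.0, 2.0, 3.0, 4.0, 5.0]))
        cleaned, flags = rhcp.clean_outliers(values)
        # Q1=2, Q3=4, lower fence 2 - 6 = -4
        assert cleaned["a"] == -4.0 and flags == ["a"]

    def test_single_value_unchanged(self):
        cleaned, flags = rhcp.clean_outliers({"only": 3.0})
        assert cleaned == {"only": 3.0} and flags == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rhcp.clean_outliers({})

    def test_missing_values_pass_through(self):
        values = {"a": 1.0, "b": float("nan"), "c": 2.0}
        cleaned, flags = rhcp.clean_outliers(values)
        assert math.isnan(cleaned["b"]) and "b" not in flags

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60))
    def test_idempotent_and_within_fences(self, vals):
        values = {str(i): v for i, v in enumerate(vals)}
        cleaned, _ = rhcp.clean_outliers(values)
        arr = np.array(list(values.values()))
        q1, q3 = np.quantile(arr, [0.25, 0.75])
        lower, upper = q1 - 3 * (q3 - q1), q3 + 3 * (q3 - q1)
        assert all(lower - 1e-9 <= v <= upper + 1e-9 for v in cleaned.values())
        again, flags2 = rhcp.clean_outliers(cleaned)
        assert again == cleaned and flags2 == []

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60))
    def test_winsorisation_never_crosses_the_median(self, vals):
        values = {str(i): v for i, v in enumerate(vals)}
        cleaned, _ = rhcp.clean_outliers(values)
        med = float(np.median(np.array(vals)))
        for k, v in values.items():
            if v > med:
                assert cleaned[k] >= med
            elif v < med:
                assert cleaned[k] <= med


class TestDistrictDistribution:
    def summary(self, values, national=0.0):
        defn = make_defn("mean")
        return rhcp.district_distribution(defn, values, national)

    def test_five_number_summary_of_1_to_5(self):
        s = self.summary({f"D{i}": float(i) for i in range(1, 6)})
        assert (s.minimum, s.q25, s.median, s.q75, s.maximum) == (1, 2, 3, 4, 5)

    def test_constant_values_collapse(self):
        s = self.summary({"D1": 7.0, "D2": 7.0, "D3": 7.0})
        assert s.minimum == s.q25 == s.median == s.q75 == s.maximum == 7.0

    def test_national_value_passed_through(self):
        s = self.summary({"D1": 1.0, "D2": 2.0}, national=42.0)
        assert s.national_value == 42.0

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            self.summary({"D1": 1.0})

    @settings(derandomize=True, max_examples=150)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=150))
    def test_matches_sort_and_interpolate_oracle(self, vals):
        s = self.summary({str(i): v for i, v in enumerate(vals)})
        assert s.minimum == min(vals)
        assert s.maximum == max(vals)
        assert s.q25 == pytest.approx(quantile_oracle(vals, 0.25), rel=1e-12, abs=1e-9)
        assert s.median == pytest.approx(quantile_oracle(vals, 0.5), rel=1e-12, abs=1e-9)
        assert s.q75 == pytest.approx(quantile_oracle(vals, 0.75), rel=1e-12, abs=1e-9)
        assert s.minimum <= s.q25 <= s.median <= s.q75 <= s.maximum

    def test_scale_equivariance_of_summary(self):
        base = {f"D{i}": float(v) for i, v in enumerate([3, 1, 4, 1, 5, 9, 2, 6])}
        s1 = self.summary(base, national=2.0)
        s2 = self.summary({k: 3.0 * v for k, v in base.items()}, national=6.0)
        for attr in ("minimum", "q25", "median", "q75", "maximum", "national_value"):
            assert getattr(s2, attr) == pytest.approx(3.0 * getattr(s1, attr), rel=1e-12)


class TestRankCatchment:
    def test_best_value_ranks_first(self):
        districts = {f"D{i}": float(i) for i in range(116)}
        assert rhcp.rank_catchment(1000.0, districts, "higher_better") == 1

    def test_tie_with_best_district_ranks_first(self):
        assert rhcp.rank_catchment(5.0, {"D1": 5.0, "D2": 1.0}, "higher_better") == 1

    def test_lower_better_reverses_direction(self):
        districts = {"D1": 1.0, "D2": 2.0, "D3": 3.0}
        assert rhcp.rank_catchment(0.5, districts, "lower_better") == 1
        assert rhcp.rank_catchment(10.0, districts, "lower_better") == 4

    def test_missing_value_gives_missing_rank(self):
        assert rhcp.rank_catchment(float("nan"), {"D1": 1.0}, "neutral") is None

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=116),
        st.floats(-1e3, 1e3),
        st.sampled_from(["higher_better", "lower_better", "neutral"]),
    )
    def test_rank_equals_one_plus_strictly_better_count(self, vals, catchment, polarity):
        districts = {str(i): v for i, v in enumerate(vals)}
        rank = rhcp.rank_catchment(catchment, districts, polarity)
        if polarity == "lower_better":
            expected = 1 + sum(1 for v in vals if v < catchment)
        else:
            expected = 1 + sum(1 for v in vals if v > catchment)
        assert rank == expected
        assert 1 <= rank <= len(vals) + 1
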