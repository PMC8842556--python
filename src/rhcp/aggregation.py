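"""Regional aggregation of municipal raw values, outlier cleaning, ranking.

A region (catchment, district, or the whole country) is a set of member
municipalities.  Each indicator declares how its municipal raw values combine
into one regional value:

``mean``
    unweighted arithmetic mean of the member municipal values (the default
    reading of "averages of all municipalities"; population weighting is
    available as a switch but off by default),
``sum``
    total over members (population, facility counts),
``ratio_of_sums``
    (sum of numerators) / (sum of denominators) x scale_per, recomputed from
    the regional totals rather than averaging municipal ratios — this keeps
    "X per Y" indicators well-defined in municipalities with zero providers
    and consistent in the singleton limit,
``nearest_facility_time``
    travel time from a distinguished location municipality to the nearest
    hosting municipality; for a region without a distinguished location
    (district, nation) the unweighted mean of the members' nearest-facility
    times is used.

Before the district distribution and rank are computed the district value set
is cleaned of outliers by Tukey-fence winsorisation (values outside
``Q3 + k*IQR`` / ``Q1 - k*IQR``, default k = 3, are set to the fence), so no
district silently disappears from the report.  Catchment values are never
winsorised: the local value must stay authentic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .catalogue import AggregationKind, IndicatorDefinition, Polarity
from .geography import MISSING, nearest_facility_times_all

DEFAULT_OUTLIER_MULTIPLIER = 3.0


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


class MissingFieldError(ValueError):
    """A raw-value field an indicator requires is absent or undefined."""


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number summary of an indicator over the districts, plus the
    national reference value.  Whiskers depict the total range of the
    (cleaned) district values; the box spans the quartiles."""

    indicator_id: str
    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float
    national_value: float
    n_regions: int


@dataclass(frozen=True)
class IndicatorResult:
    """Everything one report row needs for a single indicator."""

    indicator_id: str
    catchment_value: float
    absolute_numerator: float | None
    absolute_denominator: float | None
    distribution: DistributionSummary
    rank: int | None
    comparator_value: float | None
    cleaned_flag: bool


class IndicatorDataset:
    """Indexed view of the raw inputs shared by all aggregations.

    Pivots the long-format raw value table into per-field arrays once and
    caches one multi-source nearest-facility-time map per facility type, so
    a full-country batch reuses the same numbers as a single profile.
    """

    def __init__(
        self,
        raw_values: pd.DataFrame,
        facilities: pd.DataFrame,
        net: nx.Graph,
        municipality_ids: Iterable[str] | None = None,
    ):
        wide = raw_values.pivot(index="municipality_id", columns="field_name", values="value")
        if municipality_ids is not None:
            wide = wide.reindex(list(municipality_ids))
        self.municipality_ids: list[str] = list(wide.index)
        self._pos = {m: i for i, m in enumerate(self.municipality_ids)}
        self._fields: dict[str, np.ndarray] = {
            str(c): wide[c].to_numpy(dtype=float) for c in wide.columns
        }
        self.facilities = facilities
        self.net = net
        self._nearest: dict[str, dict[str, float]] = {}

    def has_field(self, name: str) -> bool:
        return name in self._fields

    def field_values(self, name: str, members: Iterable[str]) -> np.ndarray:
        """Values of one field over the member municipalities, in sorted
        member-id order (a canonical order keeps float sums reproducible)."""
        if name not in self._fields:
            raise MissingFieldError(f"raw value field {name!r} is not present in the input table")
        arr = self._fields[name]
        idx = []
        for m in sorted(members):
            if m not in self._pos:
                raise MissingFieldError(f"municipality {m!r} has no raw values")
            idx.append(self._pos[m])
        vals = arr[idx]
        if np.isnan(vals).any():
            bad = sorted(members)[int(np.flatnonzero(np.isnan(vals))[0])]
            raise MissingFieldError(f"field {name!r} is undefined for municipality {bad!r}")
        return vals

    def nearest_times(self, facility_type: str) -> dict[str, float]:
        if facility_type not in self._nearest:
            self._nearest[facility_type] = nearest_facility_times_all(
                self.net, self.facilities, facility_type
            )
        return self._nearest[facility_type]


def aggregate_over_dataset(
    defn: IndicatorDefinition,
    members: Iterable[str],
    data: IndicatorDataset,
    location: str | None = None,
    population_weighted: bool = False,
) -> tuple[float, float | None, float | None]:
    """Aggregate one indicator over a member set.

    Returns ``(value, absolute_numerator, absolute_denominator)``; the
    absolute counts are the raw regional totals shown in the report's
    absolute-values table (defined for sum and ratio-of-sums indicators).
    """
    members = list(members)
    if not members:
        raise ValueError("member set must not be empty")
    kind = defn.aggregation_kind
    if kind is AggregationKind.MEAN:
        vals = data.field_values(defn.numerator_field, members)
        if population_weighted:
            w = data.field_values("pop_total", members)
            value = float(np.sum(vals * w) / np.sum(w))
        else:
            value = float(np.mean(vals))
        return value, None, None
    if kind is AggregationKind.SUM:
        vals = data.field_values(defn.numerator_field, members)
        total = float(np.sum(vals))
        return total, total, None
    if kind is AggregationKind.RATIO_OF_SUMS:
        num = float(np.sum(data.field_values(defn.numerator_field, members)))
        den = float(np.sum(data.field_values(defn.denominator_field, members)))
        value = MISSING if den == 0 else num / den * defn.scale_per
        return value, num, den
    # nearest_facility_time
    times = data.nearest_times(defn.facility_type)
    if location is not None:
        return times.get(location, MISSING), None, None
    member_times = np.array([times.get(m, MISSING) for m in sorted(members)])
    finite = member_times[~np.isnan(member_times)]
    value = float(np.mean(finite)) if finite.size else MISSING
    return value, None, None


def aggregate_over_region(
    defn: IndicatorDefinition,
    members: Iterable[str],
    raw_values: pd.DataFrame,
    facilities: pd.DataFrame,
    net: nx.Graph,
    location: str | None = None,
    population_weighted: bool = False,
) -> tuple[float, float | None, float | None]:
    """Convenience wrapper building the indexed dataset on the fly."""
    data = IndicatorDataset(raw_values, facilities, net)
    return aggregate_over_dataset(defn, members, data, location, population_weighted)


def clean_outliers(
    values: Mapping[str, float], multiplier: float = DEFAULT_OUTLIER_MULTIPLIER
) -> tuple[dict[str, float], list[str]]:
    """Winsorise extreme values at Tukey fences.

    With Q1, Q3 the quartiles of the input values and IQR = Q3 - Q1, values
    above ``Q3 + multiplier*IQR`` are set to that fence and values below
    ``Q1 - multiplier*IQR`` to the lower fence.  Returns the cleaned mapping
    and the ids whose values were altered.  Idempotent; missing (NaN) values
    pass through untouched and do not influence the fences.
    """
    if not values:
        raise ValueError("clean_outliers requires at least one value")
    finite = np.array([v for v in values.values() if not _is_missing(v)], dtype=float)
    if finite.size == 0:
        return dict(values), []
    q1, q3 = np.quantile(finite, [0.25, 0.75])
    iqr = q3 - q1
    lower, upper = q1 - multiplier * iqr, q3 + multiplier * iqr
    cleaned: dict[str, float] = {}
    flags: list[str] = []
    for k, v in values.items():
        if _is_missing(v):
            cleaned[k] = v
        elif v > upper:
            cleaned[k] = float(upper)
            flags.append(k)
        elif v < lower:
            cleaned[k] = float(lower)
            flags.append(k)
        else:
            cleaned[k] = float(v)
    return cleaned, flags


def district_distribution(
    defn: IndicatorDefinition,
    district_values: Mapping[str, float],
    national_value: float,
) -> DistributionSummary:
    """Five-number summary (min, q25, median, q75, max) of the district
    values using linear interpolation between closest order statistics
    (the "type 7" quantile convention)."""
    finite = np.sort(np.array([v for v in district_values.values() if not _is_missing(v)], dtype=float))
    if finite.size < 2:
        raise ValueError("district distribution requires at least 2 non-missing district values")
    q25, med, q75 = np.quantile(finite, [0.25, 0.5, 0.75])
    return DistributionSummary(
        indicator_id=defn.indicator_id,
        minimum=float(finite[0]),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        maximum=float(finite[-1]),
        national_value=national_value,
        n_regions=int(finite.size),
    )


def rank_catchment(
    catchment_value: float,
    district_values: Mapping[str, float],
    polarity: Polarity | str,
) -> int | None:
    """Rank of the catchment when inserted among the district values.

    Rank 1 is the most favourable position under the indicator's polarity
    (highest value for higher_better and neutral, lowest for lower_better);
    ties take the best (smallest) rank.  A missing catchment value gets a
    missing rank.
    """
    if not district_values:
        raise ValueError("district_values must not be empty")
    if _is_missing(catchment_value):
        return None
    polarity = Polarity(polarity)
    finite = [v for v in district_values.values() if not _is_missing(v)]
    if polarity is Polarity.LOWER_BETTER:
        better = sum(1 for v in finite if v < catchment_value)
    else:
        better = sum(1 for v in finite if v > catchment_value)
    return 1 + better
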