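"""Indicator catalogue: the 35-indicator set behind each regional profile.

The catalogue is the declarative heart of the report generator: every
indicator carries the metadata that tells the aggregation layer how to turn
municipal raw values into a regional value (``aggregation_kind``), which raw
columns it needs, how to scale and display it, and in which direction a rank
is favourable (``polarity``).  Five domains group the indicators: demography
and socio-economics, disease prevention and risk factors, epidemiology and
mortality, health care service supply, and outpatient care utilisation.

Two metadata flags record known data limitations of the original reporting
system: ``source_granularity = "supra_municipal"`` marks the eight indicators
whose values are only available above municipality level and are interpolated
downwards (mostly health-survey items), and ``linkage_flag`` marks the four
inpatient-rate indicators that require person-level record linkage across
hospital episodes.
"""

from __future__ import annotations

import importlib.resources
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class AggregationKind(str, Enum):
    """How municipal raw values combine into one regional value."""

    MEAN = "mean"
    SUM = "sum"
    RATIO_OF_SUMS = "ratio_of_sums"
    NEAREST_FACILITY_TIME = "nearest_facility_time"


class Polarity(str, Enum):
    """Rank direction: which end of the scale is favourable."""

    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"
    NEUTRAL = "neutral"


class SourceGranularity(str, Enum):
    MUNICIPALITY = "municipality"
    SUPRA_MUNICIPAL = "supra_municipal"


class CatalogueError(ValueError):
    """Raised when a catalogue file violates the schema."""


class IndicatorDefinition(BaseModel):
    """One catalogue entry.

    ``numerator_field`` (and for ratio-of-sums indicators
    ``denominator_field``) name columns of the long-format raw value table;
    ``facility_type`` names the facility token used by travel-time and
    facility-count indicators.  ``scale_per`` is the reporting denominator
    (100000 for "per 100,000" indicators, 1 otherwise).
    """

    model_config = ConfigDict(frozen=True)

    indicator_id: str
    label: str
    domain: str
    aggregation_kind: AggregationKind
    numerator_field: str = ""
    denominator_field: str = ""
    facility_type: str = ""
    units: str = ""
    polarity: Polarity = Polarity.NEUTRAL
    scale_per: float = 1.0
    source_granularity: SourceGranularity = SourceGranularity.MUNICIPALITY
    linkage_flag: bool = False
    definition_text: str = ""

    @model_validator(mode="after")
    def _check_fields(self) -> "IndicatorDefinition":
        if self.aggregation_kind is AggregationKind.RATIO_OF_SUMS and not self.denominator_field:
            raise ValueError(
                f"indicator {self.indicator_id!r}: ratio_of_sums requires a denominator_field"
            )
        if self.aggregation_kind is AggregationKind.NEAREST_FACILITY_TIME and not self.facility_type:
            raise ValueError(
                f"indicator {self.indicator_id!r}: nearest_facility_time requires a facility_type"
            )
        if self.aggregation_kind in (AggregationKind.MEAN, AggregationKind.SUM) and not self.numerator_field:
            raise ValueError(
                f"indicator {self.indicator_id!r}: {self.aggregation_kind.value} requires a numerator_field"
            )
        return self

    @property
    def required_fields(self) -> tuple[str, ...]:
        """Raw-value columns this indicator reads (empty for travel times)."""
        fields = []
        if self.numerator_field:
            fields.append(self.numerator_field)
        if self.denominator_field:
            fields.append(self.denominator_field)
        return tuple(fields)


class Catalogue(BaseModel):
    """Ordered indicator catalogue grouped into domains."""

    model_config = ConfigDict(frozen=True)

    definitions: tuple[IndicatorDefinition, ...]
    domain_order: tuple[str, ...]

    @model_validator(mode="after")
    def _validate(self) -> "Catalogue":
        seen: set[str] = set()
        for d in self.definitions:
            if d.indicator_id in seen:
                raise ValueError(f"duplicate indicator_id: {d.indicator_id!r}")
            seen.add(d.indicator_id)
        known = set(self.domain_order)
        for d in self.definitions:
            if d.domain not in known:
                raise ValueError(
                    f"indicator {d.indicator_id!r} has unknown domain {d.domain!r}"
                )
        # definitions must be contiguous by domain, in domain_order
        domains_seen = [d.domain for d in self.definitions]
        expected: list[str] = []
        for dom in self.domain_order:
            expected.extend(d for d in domains_seen if d == dom)
        if domains_seen != expected:
            raise ValueError("definitions are not grouped contiguously in domain order")
        return self

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self) -> Iterator[IndicatorDefinition]:  # type: ignore[override]
        return iter(self.definitions)

    def __getitem__(self, indicator_id: str) -> IndicatorDefinition:
        for d in self.definitions:
            if d.indicator_id == indicator_id:
                return d
        raise KeyError(indicator_id)

    def by_label(self, label: str) -> IndicatorDefinition:
        for d in self.definitions:
            if d.label == label:
                return d
        raise KeyError(label)

    @property
    def required_fields(self) -> tuple[str, ...]:
        """All raw-value columns any indicator references, deduplicated."""
        out: list[str] = []
        for d in self.definitions:
            for f in d.required_fields:
                if f not in out:
                    out.append(f)
        return tuple(out)

    @property
    def facility_types(self) -> tuple[str, ...]:
        out: list[str] = []
        for d in self.definitions:
            if d.facility_type and d.facility_type not in out:
                out.append(d.facility_type)
        return tuple(out)

    def to_dict(self) -> dict:
        return {
            "domain_order": list(self.domain_order),
            "indicators": [
                {
                    **d.model_dump(),
                    "aggregation_kind": d.aggregation_kind.value,
                    "polarity": d.polarity.value,
                    "source_granularity": d.source_granularity.value,
                }
                for d in self.definitions
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )


def _catalogue_from_mapping(data: Mapping) -> Catalogue:
    try:
        indicators = [IndicatorDefinition(**rec) for rec in data["indicators"]]
        return Catalogue(
            definitions=tuple(indicators),
            domain_order=tuple(data["domain_order"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CatalogueError(str(exc)) from exc


def load_catalogue(path: str | Path = "default") -> Catalogue:
    """Load an indicator catalogue from a YAML/JSON file.

    ``"default"`` selects the built-in 35-indicator catalogue.  Raises
    :class:`CatalogueError` on duplicate ids, unknown aggregation kinds, or
    a ratio-of-sums indicator without a denominator.
    """
    if path == "default":
        text = (
            importlib.resources.files("rhcp.data")
            .joinpath("default_catalogue.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise CatalogueError("catalogue file must contain a mapping")
    return _catalogue_from_mapping(data)


def domain_counts(cat: Catalogue) -> dict[str, int]:
    """Number of indicators per domain, in domain order (zero included)."""
    counts = {dom: 0 for dom in cat.domain_order}
    for d in cat.definitions:
        counts[d.domain] += 1
    return counts
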