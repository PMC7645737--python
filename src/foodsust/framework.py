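"""Indicator framework: dimensions, activities, the indicator registry and score tables.

The assessment framework spans five sustainability dimensions (food security,
right to food, poverty and inequality, environmental performance,
social-ecological resilience) crossed with five food-system activity
categories (production, processing/storage, retail/trade, consumption, and
transversal indicators that span the whole value chain).  The bundled
registry encodes the 56-indicator framework used for the six-case
Kenya/Bolivia comparison; scores are ordinal ratings on a 0-4 Likert scale
with missing values allowed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Dimension",
    "ActivityCategory",
    "IndicatorDefinition",
    "IndicatorRegistry",
    "ScoreMatrix",
    "ValidationIssue",
    "ValidationReport",
    "build_registry",
    "load_default_registry",
    "validate_scores",
    "WAGE_INDICATORS",
]

#: The three wage indicators that carried N/A ratings in the original study
#: and are excluded before the ordinal PCA.
WAGE_INDICATORS = (
    "wages_large_farm",
    "wages_processing_storage",
    "wages_retail",
)


class Dimension(str, enum.Enum):
    """The five dimensions of food sustainability."""

    food_security = "food_security"
    right_to_food = "right_to_food"
    poverty_inequality = "poverty_inequality"
    environmental_performance = "environmental_performance"
    social_ecological_resilience = "social_ecological_resilience"


class ActivityCategory(str, enum.Enum):
    """Value-chain stage an indicator belongs to; ``transversal`` spans stages."""

    production = "production"
    processing_storage = "processing_storage"
    retail_trade = "retail_trade"
    consumption = "consumption"
    transversal = "transversal"


@dataclass(frozen=True)
class IndicatorDefinition:
    """One indicator of the framework: stable id, label, and its placement."""

    id: str
    label: str
    dimension: Dimension
    activity: ActivityCategory
    rating_rule_ref: str | None = None


class FrameworkError(ValueError):
    """Raised for malformed framework definitions."""


@dataclass
class IndicatorRegistry:
    """Ordered collection of indicator definitions with lookup helpers."""

    indicators: list[IndicatorDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.indicators]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise FrameworkError(f"duplicate indicator ids: {sorted(dupes)}")
        self._by_id = {ind.id: ind for ind in self.indicators}

    def __len__(self) -> int:
        return len(self.indicators)

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    def __iter__(self):
        return iter(self.indicators)

    def __getitem__(self, indicator_id: str) -> IndicatorDefinition:
        return self._by_id[indicator_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, IndicatorRegistry) and self.indicators == other.indicators

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.indicators]

    def ids_for_dimension(self, dimension: Dimension) -> list[str]:
        return [ind.id for ind in self.indicators if ind.dimension == dimension]

    def ids_for_activity(self, activity: ActivityCategory) -> list[str]:
        return [ind.id for ind in self.indicators if ind.activity == activity]

    def dimension_counts(self) -> dict[Dimension, int]:
        return {d: len(self.ids_for_dimension(d)) for d in Dimension}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "label": [i.label for i in self.indicators],
                "dimension": [i.dimension.value for i in self.indicators],
                "activity": [i.activity.value for i in self.indicators],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_registry(definition_source: str | Path | pd.DataFrame) -> IndicatorRegistry:
    """Build an :class:`IndicatorRegistry` from a columnar definition.

    Parameters
    ----------
    definition_source
        Path to a CSV with columns ``id,label,dimension,activity`` (a
        ``rating_rule_ref`` column is optional), or an equivalent DataFrame.

    Raises
    ------
    FrameworkError
        On empty input, missing columns, unknown dimension/activity names,
        or duplicate ids.
    """
    if isinstance(definition_source, pd.DataFrame):
        table = definition_source
    else:
        path = Path(definition_source)
        try:
            table = pd.read_csv(path, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise FrameworkError(f"empty framework definition: {path}") from exc
    if table.empty:
        raise FrameworkError("framework definition contains no indicator rows")
    required = {"id", "label", "dimension", "activity"}
    missing = required - set(table.columns)
    if missing:
        raise FrameworkError(f"framework definition missing columns: {sorted(missing)}")

    indicators: list[IndicatorDefinition] = []
    for row_number, row in enumerate(table.itertuples(index=False), start=2):
        if any(pd.isna(getattr(row, col)) for col in ("id", "label", "dimension", "activity")):
            raise FrameworkError(f"malformed framework row {row_number}: missing field")
        try:
            dimension = Dimension(row.dimension)
        except ValueError as exc:
            raise FrameworkError(
                f"framework row {row_number}: unknown dimension {row.dimension!r}"
            ) from exc
        try:
            activity = ActivityCategory(row.activity)
        except ValueError as exc:
            raise FrameworkError(
                f"framework row {row_number}: unknown activity {row.activity!r}"
            ) from exc
        rule_ref = getattr(row, "rating_rule_ref", None)
        if rule_ref is not None and pd.isna(rule_ref):
            rule_ref = None
        indicators.append(
            IndicatorDefinition(
                id=str(row.id),
                label=str(row.label),
                dimension=dimension,
                activity=activity,
                rating_rule_ref=rule_ref,
            )
        )
    return IndicatorRegistry(indicators)


def load_default_registry() -> IndicatorRegistry:
    """Load the bundled 56-indicator framework."""
    source = resources.files("foodsust.data").joinpath("indicator_framework.csv")
    with resources.as_file(source) as path:
        return build_registry(path)


class ScoreMatrix:
    """Ordinal 0-4 scores per (food system, indicator), missing allowed.

    Internally a float DataFrame indexed by indicator id with one column per
    food system; missing scores are NaN.
    """

    VALID_SCORES = frozenset({0, 1, 2, 3, 4})

    def __init__(self, scores: pd.DataFrame):
        self.scores = scores.astype(float)

    @classmethod
    def from_dict(
        cls, data: Mapping[str, Mapping[str, float | None]], indicator_order: Iterable[str] | None = None
    ) -> "ScoreMatrix":
        """Build from ``{system: {indicator_id: score-or-None}}``."""
        frame = pd.DataFrame(data, dtype=float)
        if indicator_order is not None:
            frame = frame.reindex(list(indicator_order))
        return cls(frame)

    @property
    def food_systems(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.scores.index)

    def system_scores(self, system: str) -> pd.Series:
        if system not in self.scores.columns:
            raise KeyError(f"unknown food system: {system}")
        return self.scores[system]

    def copy(self) -> "ScoreMatrix":
        return ScoreMatrix(self.scores.copy())

    def equals(self, other: "ScoreMatrix") -> bool:
        return self.scores.equals(other.scores)

    def __repr__(self) -> str:
        return (
            f"ScoreMatrix({len(self.indicator_ids)} indicators x "
            f"{len(self.food_systems)} food systems)"
        )


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    location: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(issue.severity == "error" for issue in self.issues)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]


def validate_scores(matrix: ScoreMatrix, registry: IndicatorRegistry) -> ValidationReport:
    """Check a score matrix against the registry; reports, never raises.

    Flags unknown indicator ids, non-ordinal or out-of-range scores, and food
    systems whose scores are entirely missing for some dimension.  Pure
    function: inputs are never mutated.
    """
    issues: list[ValidationIssue] = []
    known = set(registry.ids)
    for indicator_id in matrix.indicator_ids:
        if indicator_id not in known:
            issues.append(
                ValidationIssue(
                    "error", f"indicator {indicator_id}", "indicator id not in registry"
                )
            )
    for system in matrix.food_systems:
        col = matrix.scores[system]
        for indicator_id, value in col.items():
            if pd.isna(value):
                continue
            if value != int(value) or int(value) not in ScoreMatrix.VALID_SCORES:
                issues.append(
                    ValidationIssue(
                        "error",
                        f"({system}, {indicator_id})",
                        f"score {value} outside the ordinal scale 0-4",
                    )
                )
        for dimension in Dimension:
            ids = [i for i in registry.ids_for_dimension(dimension) if i in col.index]
            if ids and col.loc[ids].isna().all():
                issues.append(
                    ValidationIssue(
                        "warning",
                        f"({system}, {dimension.value})",
                        "all scores missing for this dimension",
                    )
                )
    return ValidationReport(issues)
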