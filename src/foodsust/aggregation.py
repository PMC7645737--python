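"""Aggregation of indicator scores: dimension medians, overall score, activity profiles.

Medians are the aggregation operator throughout, because the 0-4 scale is
ordinal: equal intervals between rating values cannot be assumed, so means of
raw scores are avoided.  The overall food-sustainability score of one food
system is the arithmetic mean of its five dimension medians.  A second view
groups the same indicator scores by value-chain activity; summing the five
activity medians gives a cumulative score out of a maximum of 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .framework import ActivityCategory, Dimension, IndicatorRegistry, ScoreMatrix

__all__ = [
    "SustainabilityProfile",
    "ActivityProfile",
    "FiveNumberSummary",
    "dimension_medians",
    "overall_score",
    "sustainability_profile",
    "activity_profile",
    "score_distribution",
    "assess_all",
]


@dataclass(frozen=True)
class SustainabilityProfile:
    """One food system's five dimension medians and overall score."""

    system: str
    dimension_medians: dict[Dimension, float]
    overall: float

    def rounded(self, decimals: int = 1) -> dict[str, float]:
        """Display form: half-up rounding applied only at reporting time."""
        out = {
            d.value: _round_display(m, decimals) for d, m in self.dimension_medians.items()
        }
        out["overall"] = _round_display(self.overall, decimals)
        return out


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


@dataclass(frozen=True)
class ActivityProfile:
    """Per-activity medians, the cumulative (max 20) score, and quartile summaries."""

    system: str
    activity_medians: dict[ActivityCategory, float]
    cumulative: float
    summaries: dict[ActivityCategory, FiveNumberSummary]
    empty_activities: tuple[ActivityCategory, ...] = field(default=())


def _round_display(x: float, decimals: int = 1) -> float:
    factor = 10**decimals
    return np.floor(x * factor + 0.5) / factor


def _median(values: np.ndarray) -> float:
    # midpoint of the two central order statistics for even counts
    return float(np.median(values))


def dimension_medians(
    matrix: ScoreMatrix, registry: IndicatorRegistry, system: str
) -> dict[Dimension, float]:
    """Median of each dimension's non-missing indicator scores for one system.

    Raises if a dimension has no non-missing score: a food system cannot be
    profiled on a dimension it carries no evidence for.
    """
    col = matrix.system_scores(system)
    medians: dict[Dimension, float] = {}
    for dimension in Dimension:
        ids = [i for i in registry.ids_for_dimension(dimension) if i in col.index]
        values = col.loc[ids].dropna().to_numpy() if ids else np.array([])
        if values.size == 0:
            raise ValueError(
                f"food system {system}: no scores available for dimension {dimension.value}"
            )
        medians[dimension] = _median(values)
    return medians


def overall_score(medians: dict[Dimension, float]) -> float:
    """Arithmetic mean of the five dimension medians."""
    missing = [d for d in Dimension if d not in medians]
    if missing:
        raise ValueError(f"missing dimension medians: {[d.value for d in missing]}")
    values = [medians[d] for d in Dimension]
    if any(not 0 <= v <= 4 for v in values):
        raise ValueError("dimension medians must lie in [0, 4]")
    return float(np.mean(values))


def sustainability_profile(
    matrix: ScoreMatrix, registry: IndicatorRegistry, system: str
) -> SustainabilityProfile:
    medians = dimension_medians(matrix, registry, system)
    return SustainabilityProfile(system, medians, overall_score(medians))


def activity_profile(
    matrix: ScoreMatrix, registry: IndicatorRegistry, system: str
) -> ActivityProfile:
    """Group one system's scores by activity: medians, quartiles, cumulative score.

    An activity with no non-missing scores contributes 0 to the cumulative
    score and is flagged in ``empty_activities`` rather than raising.
    """
    col = matrix.system_scores(system)
    medians: dict[ActivityCategory, float] = {}
    summaries: dict[ActivityCategory, FiveNumberSummary] = {}
    empty: list[ActivityCategory] = []
    for activity in ActivityCategory:
        ids = [i for i in registry.ids_for_activity(activity) if i in col.index]
        values = col.loc[ids].dropna().to_numpy() if ids else np.array([])
        if values.size == 0:
            empty.append(activity)
            medians[activity] = 0.0
            summaries[activity] = FiveNumberSummary(np.nan, np.nan, np.nan, np.nan, np.nan)
            continue
        medians[activity] = _median(values)
        q = np.percentile(values, [0, 25, 50, 75, 100], method="linear")
        summaries[activity] = FiveNumberSummary(*map(float, q))
    cumulative = float(sum(medians.values()))
    return ActivityProfile(system, medians, cumulative, summaries, tuple(empty))


def score_distribution(
    matrix: ScoreMatrix, registry: IndicatorRegistry, system: str
) -> dict[ActivityCategory, FiveNumberSummary]:
    """Five-number summaries (min, Q1, median, Q3, max) per activity."""
    return activity_profile(matrix, registry, system).summaries


def assess_all(matrix: ScoreMatrix, registry: IndicatorRegistry) -> pd.DataFrame:
    """Sustainability profiles for every food system, as a tidy table.

    One row per system; columns are the five dimension medians and the
    overall score (unrounded).
    """
    rows = []
    for system in matrix.food_systems:
        profile = sustainability_profile(matrix, registry, system)
        row = {"system": system}
        row.update({d.value: m for d, m in profile.dimension_medians.items()})
        row["overall"] = profile.overall
        rows.append(row)
    return pd.DataFrame(rows).set_index("system")
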