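"""Key-lever analysis: how often each indicator deviates from its system's median.

For every food system a reference median is taken over all its non-missing
indicator scores.  Each indicator is then classified, system by system, as
scoring below, above, or equal to that reference.  Indicators that fall below
the reference in most systems are "key levers": structural weak points shared
across food systems and hence priorities for policy intervention.  The
symmetric above-the-median counts identify shared strengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .framework import ScoreMatrix

__all__ = [
    "DeviationCounts",
    "DeviationTable",
    "reference_median",
    "deviation_table",
    "rank_levers",
    "LeverReport",
]


@dataclass(frozen=True)
class DeviationCounts:
    indicator: str
    n_below: int
    n_above: int
    n_equal: int
    n_missing: int

    @property
    def total(self) -> int:
        return self.n_below + self.n_above + self.n_equal + self.n_missing


@dataclass
class DeviationTable:
    """Per-indicator below/above/equal/missing counts across food systems."""

    counts: dict[str, DeviationCounts]
    n_systems: int

    def __getitem__(self, indicator: str) -> DeviationCounts:
        return self.counts[indicator]

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": list(self.counts),
                "n_below": [c.n_below for c in self.counts.values()],
                "n_above": [c.n_above for c in self.counts.values()],
                "n_equal": [c.n_equal for c in self.counts.values()],
                "n_missing": [c.n_missing for c in self.counts.values()],
            }
        ).set_index("indicator")

    def to_diverging(self) -> pd.DataFrame:
        """Tidy (indicator, side, count) table for a diverging-bar chart."""
        rows = []
        for indicator, c in self.counts.items():
            rows.append({"indicator": indicator, "side": "below", "count": c.n_below})
            rows.append({"indicator": indicator, "side": "above", "count": c.n_above})
        return pd.DataFrame(rows)


def reference_median(matrix: ScoreMatrix, system: str) -> float:
    """Median of all non-missing indicator scores of one food system."""
    values = matrix.system_scores(system).dropna().to_numpy()
    if values.size == 0:
        raise ValueError(f"food system {system} has no non-missing scores")
    return float(np.median(values))


def deviation_table(matrix: ScoreMatrix) -> DeviationTable:
    """Classify every (system, indicator) cell against the system's reference median."""
    refs = {system: reference_median(matrix, system) for system in matrix.food_systems}
    counts: dict[str, DeviationCounts] = {}
    for indicator in matrix.indicator_ids:
        below = above = equal = missing = 0
        for system in matrix.food_systems:
            value = matrix.scores.at[indicator, system]
            if pd.isna(value):
                missing += 1
            elif value < refs[system]:
                below += 1
            elif value > refs[system]:
                above += 1
            else:
                equal += 1
        counts[indicator] = DeviationCounts(indicator, below, above, equal, missing)
    return DeviationTable(counts, len(matrix.food_systems))


@dataclass(frozen=True)
class LeverReport:
    """Indicators ranked by shared weakness and by shared strength."""

    worst_first: tuple[str, ...]
    best_first: tuple[str, ...]
    no_positive_score: frozenset[str]  # indicators never above any reference median


def rank_levers(table: DeviationTable) -> LeverReport:
    """Rank indicators worst-first by below-median count and best-first by above.

    Ties on n_below break by fewer above-median scores (weaker overall), then
    lexicographically by id, giving a deterministic total order.
    """
    if not table.counts:
        raise ValueError("empty deviation table")
    worst = sorted(
        table.counts.values(), key=lambda c: (-c.n_below, c.n_above, c.indicator)
    )
    best = sorted(
        table.counts.values(), key=lambda c: (-c.n_above, c.n_below, c.indicator)
    )
    return LeverReport(
        worst_first=tuple(c.indicator for c in worst),
        best_first=tuple(c.indicator for c in best),
        no_positive_score=frozenset(
            c.indicator for c in table.counts.values() if c.n_above == 0
        ),
    )
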