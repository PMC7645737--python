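"""Rating engine: convert raw indicator measurements to the 0-4 Likert scale.

Quantitative indicators are normalised either against an official benchmark
(e.g. the minimum wage) or against the maximum value observed in the study
context (the "100% value"), then mapped linearly onto the five-point scale.
Qualitative indicators are mapped through an explicit category table agreed
per indicator.  The household food-insecurity flag uses the lightest item of
the experience-based scales (ELCSA/HFIAS): whether the household worried
about not having enough food in the past four weeks.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Direction",
    "RatingRule",
    "MISSING",
    "score_from_fraction",
    "score_relative_to_max",
    "score_against_benchmark",
    "score_qualitative",
    "food_insecurity_flag",
    "insecurity_prevalence",
]

#: Sentinel for a missing ordinal score.
MISSING = None


class Direction(str, enum.Enum):
    higher_is_better = "higher_is_better"
    lower_is_better = "lower_is_better"


class RuleKind(str, enum.Enum):
    benchmark = "benchmark"
    max_in_context = "max_in_context"
    qualitative = "qualitative"


@dataclass(frozen=True)
class RatingRule:
    """How one indicator's raw measurement becomes a 0-4 score.

    ``benchmark`` rules carry the value treated as 100% attainment;
    ``qualitative`` rules carry a category->score map; ``max_in_context``
    rules normalise against the largest value observed in the dataset.
    """

    kind: RuleKind
    direction: Direction = Direction.higher_is_better
    benchmark_value: float | None = None
    category_map: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kind = RuleKind(self.kind)
        if kind is RuleKind.benchmark and self.benchmark_value is None:
            raise ValueError("benchmark rule requires benchmark_value")
        if kind is not RuleKind.benchmark and self.benchmark_value is not None:
            raise ValueError("benchmark_value only valid for benchmark rules")
        if kind is RuleKind.qualitative:
            if not self.category_map:
                raise ValueError("qualitative rule requires a category_map")
            bad = {k: v for k, v in self.category_map.items() if v not in range(5)}
            if bad:
                raise ValueError(f"category_map scores outside 0-4: {bad}")
        elif self.category_map:
            raise ValueError("category_map only valid for qualitative rules")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def score_from_fraction(p: float, direction: Direction = Direction.higher_is_better) -> int:
    """Map an attainment fraction in [0, 1] linearly onto the 0-4 scale.

    The scale equates 0-4 with 0-100%: score = round-half-up(4p) when higher
    values are desirable, and the mirror image when lower values are.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {p}")
    if Direction(direction) is Direction.lower_is_better:
        p = 1.0 - p
    return _round_half_up(4.0 * p)


def score_relative_to_max(
    value: float, context_max: float, direction: Direction = Direction.higher_is_better
) -> int:
    """Score a measurement against the maximum value found in its context.

    The context maximum plays the role of the 100% value; measurements above
    it (possible when the maximum comes from a different sub-sample) are
    capped at full attainment.
    """
    if context_max <= 0:
        raise ValueError(f"context maximum must be positive, got {context_max}")
    if value < 0:
        raise ValueError(f"measurement must be non-negative, got {value}")
    return score_from_fraction(min(value / context_max, 1.0), direction)


def score_against_benchmark(value: float, rule: RatingRule) -> int:
    """Score a measurement against an official benchmark (e.g. minimum wage).

    Attainment is ``value / benchmark`` capped at 100%; direction follows the
    rule.
    """
    if RuleKind(rule.kind) is not RuleKind.benchmark:
        raise ValueError("rule is not a benchmark rule")
    if rule.benchmark_value is None or rule.benchmark_value <= 0:
        raise ValueError("benchmark rule requires a positive benchmark_value")
    if value < 0:
        raise ValueError(f"measurement must be non-negative, got {value}")
    fraction = min(value / rule.benchmark_value, 1.0)
    return score_from_fraction(fraction, rule.direction)


def score_qualitative(state_label: str, rule: RatingRule) -> int | None:
    """Look up the agreed score for a qualitative state label.

    Unmapped labels yield a missing score with a warning rather than an
    error, so that one unrecognised label does not abort a whole import.
    """
    if RuleKind(rule.kind) is not RuleKind.qualitative:
        raise ValueError("rule is not a qualitative rule")
    if state_label in rule.category_map:
        return rule.category_map[state_label]
    warnings.warn(
        f"qualitative state {state_label!r} has no mapped score; recording as missing",
        stacklevel=2,
    )
    return MISSING


_YES = {"yes", "y", "true", "1"}
_NO = {"no", "n", "false", "0"}


def food_insecurity_flag(worry_response: str | bool) -> bool:
    """Household food-insecurity flag from the lightest experience-scale item.

    True iff the household reported worrying, in the past four weeks, that it
    would not have enough food.
    """
    if isinstance(worry_response, bool):
        return worry_response
    token = str(worry_response).strip().lower()
    if token in _YES:
        return True
    if token in _NO:
        return False
    raise ValueError(f"expected a yes/no response, got {worry_response!r}")


def insecurity_prevalence(responses: Iterable[str | bool]) -> float:
    """Share of households flagged food-insecure among the given responses."""
    flags = [food_insecurity_flag(r) for r in responses]
    if not flags:
        raise ValueError("no responses given")
    return sum(flags) / len(flags)
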