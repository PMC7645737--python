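"""Agroecosystem Service Capacity index and Shannon diversity.

The Agroecosystem Service Capacity (ASC) of a land-cover class combines the
number of agroecosystem services it can provide (Ni, out of a catalogue of
23 services defined over up to 99 land-cover classes), the mean strength
with which it provides them (Si), and the share of the agroecosystem's area
it occupies (Ai):

    ASC_i = ((S_i + N_i) / 2) * A_i

The index for a whole agroecosystem (a farm, a landscape) is the sum over
its classes, ASCI = sum_i ASC_i.  Area shares are stored as fractions in
[0, 1]; tables giving percentages are divided by 100 on import.  ASCI enters
the environmental-performance dimension after max-in-context normalisation,
which makes the result invariant to that scale choice.

Shannon diversity H = -sum p_i ln p_i over crop/breed counts feeds the
agrobiodiversity indicators of the resilience dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "N_SERVICES",
    "MAX_CLASSES",
    "LandCoverClass",
    "AgroecosystemProfile",
    "compute_asc",
    "compute_asci",
    "shannon_index",
    "classes_from_strengths",
]

#: Size of the agroecosystem-service catalogue.
N_SERVICES = 23
#: Number of land-cover classes the catalogue distinguishes.
MAX_CLASSES = 99

_AREA_TOL = 1e-9


@dataclass(frozen=True)
class LandCoverClass:
    """One land-cover class: area share, service count, mean service strength."""

    name: str
    area_share: float  # Ai, fraction of the agroecosystem in [0, 1]
    n_services: int  # Ni, services the class can provide, 0..23
    strength: float  # Si, mean provision strength, >= 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_share <= 1.0:
            raise ValueError(f"{self.name}: area share must lie in [0, 1], got {self.area_share}")
        if not 0 <= self.n_services <= N_SERVICES:
            raise ValueError(
                f"{self.name}: service count must lie in [0, {N_SERVICES}], got {self.n_services}"
            )
        if self.strength < 0:
            raise ValueError(f"{self.name}: strength must be non-negative, got {self.strength}")


def compute_asc(c: LandCoverClass) -> float:
    """Agroecosystem Service Capacity of one class: ((Si + Ni) / 2) * Ai."""
    return ((c.strength + c.n_services) / 2.0) * c.area_share


def compute_asci(classes: Iterable[LandCoverClass]) -> float:
    """ASCI of an agroecosystem: the sum of per-class capacities.

    Area shares may sum to less than 1 (unmapped area contributes nothing)
    but never more.
    """
    classes = list(classes)
    total_area = sum(c.area_share for c in classes)
    if total_area > 1.0 + _AREA_TOL:
        raise ValueError(f"area shares sum to {total_area:.6f} > 1")
    return float(sum(compute_asc(c) for c in classes))


@dataclass
class AgroecosystemProfile:
    """A set of land-cover classes and their aggregate service-capacity index."""

    classes: list[LandCoverClass] = field(default_factory=list)

    @property
    def asci(self) -> float:
        return compute_asci(self.classes)


def classes_from_strengths(
    names: Sequence[str], area_shares: Sequence[float], strength_table: np.ndarray
) -> list[LandCoverClass]:
    """Derive (Ni, Si) from a class x service strength matrix.

    Ni is the number of services with positive strength; Si their mean
    strength (over provided services only).
    """
    strength_table = np.asarray(strength_table, dtype=float)
    if strength_table.shape != (len(names), strength_table.shape[1]):
        raise ValueError("strength table must have one row per class")
    classes = []
    for name, area, row in zip(names, area_shares, strength_table):
        provided = row[row > 0]
        n_services = int(provided.size)
        strength = float(provided.mean()) if n_services else 0.0
        classes.append(LandCoverClass(name, float(area), n_services, strength))
    return classes


def shannon_index(counts: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i over labels with positive count."""
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float
    )
    if values.size == 0 or (values < 0).any():
        raise ValueError("counts must be non-negative and non-empty")
    total = values.sum()
    if total <= 0:
        raise ValueError("at least one positive count required")
    p = values[values > 0] / total
    return float(-(p * np.log(p)).sum())
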