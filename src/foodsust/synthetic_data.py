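"""Synthetic inputs for every pipeline stage: score matrices, ordinal data, landscapes.

Three generators close the loop between the modules and their tests without
any external data:

* ``simulate_scores`` draws 0-4 score matrices for six food-system
  archetypes whose dimension profiles follow the qualitative patterns of
  the Kenya/Bolivia comparison: agroecological and local systems high and
  balanced; the regional system intermediate; the domestic-indigenous
  system very strong environmentally but weak on poverty and inequality;
  the two agro-industrial systems weak on environment and right to food yet
  medium-to-high on social-ecological resilience.  Missing values land
  preferentially in the three wage indicators, mirroring the N/A pattern of
  the original dataset.
* ``simulate_ordinal`` draws latent multivariate-normal data discretised at
  known thresholds — the ground-truth harness for polychoric recovery.
* ``simulate_landscape`` draws Dirichlet area shares with random service
  counts and strengths for the ASCI calculator.

All generators take an explicit seed and use numpy's PCG64 generator, so a
given seed reproduces outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .framework import (
    Dimension,
    IndicatorRegistry,
    ScoreMatrix,
    WAGE_INDICATORS,
    load_default_registry,
)
from .metrics import LandCoverClass, N_SERVICES

__all__ = [
    "ArchetypeSpec",
    "LatentSpec",
    "default_archetypes",
    "simulate_scores",
    "simulate_ordinal",
    "simulate_landscape",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Target dimension profile for one food-system archetype."""

    system: str
    targets: dict[Dimension, float]  # central score per dimension, 0-4
    missingness: float = 0.0  # background missing rate outside wage indicators
    wage_missingness: float = 0.0  # missing rate within the wage indicators

    def __post_init__(self) -> None:
        for d, t in self.targets.items():
            if not 0.0 <= t <= 4.0:
                raise ValueError(f"{self.system}/{d.value}: target {t} outside [0, 4]")
        if not 0.0 <= self.missingness <= 0.3:
            raise ValueError(f"background missingness {self.missingness} outside [0, 0.3]")
        if not 0.0 <= self.wage_missingness <= 1.0:
            raise ValueError(f"wage missingness {self.wage_missingness} outside [0, 1]")


def default_archetypes(
    missingness: float = 0.02, wage_missingness: float = 0.5
) -> list[ArchetypeSpec]:
    """Six archetypes spanning the study's food-system types.

    Targets encode the qualitative dimension patterns of the six case
    studies on the 0-4 scale (half-point resolution); missingness defaults
    put roughly 5-10%% of cells to N/A overall, concentrated in the three
    wage indicators.
    """
    D = Dimension
    profiles = {
        "B1": {  # agro-industrial (soy): weak environment & right to food, medium resilience
            D.food_security: 2.0,
            D.right_to_food: 1.5,
            D.poverty_inequality: 2.0,
            D.environmental_performance: 1.0,
            D.social_ecological_resilience: 2.5,
        },
        "B2": {  # domestic-indigenous: top environment, weak poverty/inequality
            D.food_security: 3.0,
            D.right_to_food: 2.5,
            D.poverty_inequality: 1.5,
            D.environmental_performance: 4.0,
            D.social_ecological_resilience: 3.0,
        },
        "B3": {  # agroecological: high and balanced
            D.food_security: 3.5,
            D.right_to_food: 3.0,
            D.poverty_inequality: 3.0,
            D.environmental_performance: 4.0,
            D.social_ecological_resilience: 3.5,
        },
        "K1": {  # agro-industrial (export horticulture): above-medium resilience
            D.food_security: 1.5,
            D.right_to_food: 1.5,
            D.poverty_inequality: 2.5,
            D.environmental_performance: 1.0,
            D.social_ecological_resilience: 3.0,
        },
        "K2": {  # regional: intermediate throughout
            D.food_security: 2.5,
            D.right_to_food: 2.0,
            D.poverty_inequality: 2.0,
            D.environmental_performance: 2.5,
            D.social_ecological_resilience: 3.0,
        },
        "K3": {  # local: balanced medium-high
            D.food_security: 3.0,
            D.right_to_food: 3.0,
            D.poverty_inequality: 3.0,
            D.environmental_performance: 3.0,
            D.social_ecological_resilience: 3.0,
        },
    }
    return [
        ArchetypeSpec(system, targets, missingness, wage_missingness)
        for system, targets in profiles.items()
    ]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def simulate_scores(
    specs: list[ArchetypeSpec] | None = None,
    registry: IndicatorRegistry | None = None,
    noise_sd: float = 0.8,
    seed: int = 0,
) -> ScoreMatrix:
    """Draw an ordinal score matrix for the given archetypes.

    Each score is a normal draw centred on the archetype's dimension target
    (sd ``noise_sd``), rounded half-up and clipped to {0..4} — a discretised
    truncated normal on the Likert grid.  Missing values are planted by the
    per-spec rates, preferentially in the wage indicators.
    """
    if specs is None:
        specs = default_archetypes()
    if registry is None:
        registry = load_default_registry()
    rng = np.random.default_rng(seed)
    ids = registry.ids
    dim_of = {ind.id: ind.dimension for ind in registry}
    wage_set = set(WAGE_INDICATORS)

    columns: dict[str, np.ndarray] = {}
    for spec in specs:
        targets = np.array([spec.targets[dim_of[i]] for i in ids])
        if noise_sd > 0:
            draw = rng.normal(targets, noise_sd)
        else:
            draw = targets.copy()
        scores = np.clip(_round_half_up(draw), 0, 4)
        for idx, indicator in enumerate(ids):
            rate = spec.wage_missingness if indicator in wage_set else spec.missingness
            if rate > 0 and rng.random() < rate:
                scores[idx] = np.nan
        columns[spec.system] = scores
    frame = pd.DataFrame(columns, index=ids)
    return ScoreMatrix(frame)


@dataclass(frozen=True)
class LatentSpec:
    """Latent-Gaussian ordinal model: correlation, thresholds, sample size."""

    correlation: np.ndarray
    thresholds: list[np.ndarray] = field(default_factory=list)  # per-variable, ascending
    n: int = 1000

    def __post_init__(self) -> None:
        corr = np.asarray(self.correlation, dtype=float)
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        for tau in self.thresholds:
            if np.any(np.diff(tau) <= 0):
                raise ValueError("thresholds must be strictly ascending")


def simulate_ordinal(spec: LatentSpec, seed: int = 0) -> np.ndarray:
    """Draw n ordinal vectors by thresholding latent multivariate normals.

    Returns an (n, p) integer array; category k is the number of thresholds
    the latent draw exceeds.
    """
    corr = np.asarray(spec.correlation, dtype=float)
    p = corr.shape[0]
    thresholds = spec.thresholds or [np.array([-0.8416, -0.2533, 0.2533, 0.8416])] * p
    if len(thresholds) != p:
        raise ValueError("one threshold vector per variable required")
    rng = np.random.default_rng(seed)
    latent = rng.multivariate_normal(np.zeros(p), corr, size=spec.n, method="cholesky")
    out = np.empty_like(latent, dtype=int)
    for j in range(p):
        out[:, j] = np.searchsorted(thresholds[j], latent[:, j], side="left")
    return out


def simulate_landscape(n_classes: int, seed: int = 0) -> list[LandCoverClass]:
    """Draw a toy landscape: Dirichlet area shares, random Ni and Si per class."""
    if not 1 <= n_classes <= 99:
        raise ValueError(f"n_classes must lie in [1, 99], got {n_classes}")
    rng = np.random.default_rng(seed)
    shares = rng.dirichlet(np.ones(n_classes))
    classes = []
    for i in range(n_classes):
        n_services = int(rng.integers(0, N_SERVICES + 1))
        strength = float(rng.uniform(0.0, 5.0)) if n_services else 0.0
        classes.append(
            LandCoverClass(f"class_{i + 1:02d}", float(shares[i]), n_services, strength)
        )
    return classes
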