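import numpy as np
import pandas as pd
import pytest

from foodsust.framework import ScoreMatrix, load_default_registry


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture()
def full_matrix(registry):
    """Complete 56 x 6 matrix with deterministic pseudo-random valid scores."""
    rng = np.random.default_rng(7)
    systems = ["B1", "B2", "B3", "K1", "K2", "K3"]
    frame = pd.DataFrame(
        rng.integers(0, 5, size=(len(registry.ids), len(systems))).astype(float),
        index=registry.ids,
        columns=systems,
    )
    return ScoreMatrix(frame)


def random_matrix(rng, n_indicators=8, n_systems=4, missing_rate=0.0):
    """Small random score matrix for property tests."""
    frame = pd.DataFrame(
        rng.integers(0, 5, size=(n_indicators, n_systems)).astype(float),
        index=[f"ind_{i}" for i in range(n_indicators)],
        columns=[f"S{j}" for j in range(n_systems)],
    )
    if missing_rate > 0:
        mask = rng.random(frame.shape) < missing_rate
        frame = frame.mask(mask)
    return ScoreMatrix(frame)
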