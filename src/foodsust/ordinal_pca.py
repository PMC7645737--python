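"""Polychoric correlation and principal component analysis for ordinal scores.

The 0-4 ratings are ordinal, so Pearson correlations on the raw codes are
biased towards zero.  The polychoric model instead assumes each ordinal
variable arises by cutting a latent standard-normal variable at unknown
thresholds; the correlation of interest is that of the latent variables.
Estimation is two-step maximum likelihood: thresholds are fixed at the
normal quantiles of the marginal cumulative proportions, then the latent
correlation maximises the multinomial likelihood whose cell probabilities
are bivariate-normal rectangle probabilities over the threshold grid.

PCA is performed on the assembled polychoric correlation matrix.  With few
observations (six food systems in the motivating study) the pairwise matrix
is usually indefinite; it is repaired by eigenvalue clipping before the
eigendecomposition.  Components are retained by the Kaiser criterion
(eigenvalue > 1), capped at n_observations - 1, and each retained
component's influential indicators are those with |loading| above a cutoff
(0.45 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .framework import ScoreMatrix

__all__ = [
    "bivariate_normal_cdf",
    "na_filter",
    "estimate_thresholds",
    "polychoric_corr",
    "polychoric_matrix",
    "PolychoricMatrix",
    "pca_correlation",
    "PCAResult",
    "retain_components",
    "influential_indicators",
    "run_ordinal_pca",
]

_RHO_BOUND = 0.999
_RHO_TOL = 1e-6
_MIN_CELL_PROB = 1e-12


def bivariate_normal_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for a standard bivariate normal with correlation rho.

    Owen's T-function formulation; exact up to the accuracy of
    ``scipy.special.owens_t`` (well below 1e-7).  ``h`` and ``k`` broadcast;
    infinite bounds are handled.
    """
    scalar_input = np.isscalar(h) and np.isscalar(k)
    h = np.atleast_1d(np.asarray(h, dtype=float))
    k = np.atleast_1d(np.asarray(k, dtype=float))
    h, k = np.broadcast_arrays(h, k)
    if abs(rho) >= 1.0 or rho == 0.0:
        if rho >= 1.0:
            out = np.minimum(stats.norm.cdf(h), stats.norm.cdf(k))
        elif rho <= -1.0:
            out = np.maximum(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0)
        else:
            out = stats.norm.cdf(h) * stats.norm.cdf(k)
        return float(out[0]) if scalar_input else out

    # infinite bounds reduce to univariate margins
    out = np.empty(h.shape, dtype=float)
    inf_mask = np.isinf(h) | np.isinf(k)
    if inf_mask.any():
        hi, ki = h[inf_mask], k[inf_mask]
        # an infinite upper bound drops out of the probability
        res = np.where(
            (hi == -np.inf) | (ki == -np.inf),
            0.0,
            stats.norm.cdf(np.where(hi == np.inf, ki, hi)),
        )
        out[inf_mask] = res

    fin = ~inf_mask
    hf = h[fin].copy()
    kf = k[fin].copy()
    # exact zeros: take the limit from above (the CDF is continuous)
    tiny = 1e-15
    hf[hf == 0.0] = tiny
    kf[kf == 0.0] = tiny
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (kf - rho * hf) / (hf * denom)
    a_k = (hf - rho * kf) / (kf * denom)
    beta = np.where(hf * kf < 0.0, 0.5, 0.0)
    val = (
        0.5 * (stats.norm.cdf(hf) + stats.norm.cdf(kf))
        - special.owens_t(hf, a_h)
        - special.owens_t(kf, a_k)
        - beta
    )
    out[fin] = np.clip(val, 0.0, 1.0)
    return float(out[0]) if scalar_input else out


def na_filter(matrix: ScoreMatrix) -> tuple[ScoreMatrix, list[str]]:
    """Drop every indicator carrying at least one missing score.

    Pairwise-complete estimation is avoided: with a handful of observations
    each pairwise sample would differ, so indicators with any N/A are removed
    outright before the correlation analysis.
    """
    has_na = matrix.scores.isna().any(axis=1)
    excluded = list(matrix.scores.index[has_na])
    kept = matrix.scores.loc[~has_na]
    if kept.empty:
        raise ValueError("every indicator has missing scores; nothing left to analyse")
    return ScoreMatrix(kept), excluded


def estimate_thresholds(category_counts) -> np.ndarray:
    """Latent normal cut-points from marginal category counts.

    For counts over the ordered categories, threshold k is the standard
    normal quantile of the cumulative proportion through category k (the top
    category has no threshold).
    """
    counts = np.asarray(category_counts, dtype=float)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("category counts must be a 1-D non-negative array")
    total = counts.sum()
    if total <= 0:
        raise ValueError("no observations in category counts")
    observed = counts > 0
    if observed.sum() < 2:
        raise ValueError("variable is degenerate: fewer than two observed categories")
    cum = np.cumsum(counts)[:-1] / total
    tau = stats.norm.ppf(cum)
    return tau


def _table_loglik(rho: float, tau1: np.ndarray, tau2: np.ndarray, table: np.ndarray) -> float:
    """Multinomial log-likelihood of the contingency table at latent correlation rho."""
    g1 = np.concatenate(([-np.inf], tau1, [np.inf]))
    g2 = np.concatenate(([-np.inf], tau2, [np.inf]))
    H, K = np.meshgrid(g1, g2, indexing="ij")
    cdf = bivariate_normal_cdf(H, K, rho)
    probs = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    probs = np.clip(probs, _MIN_CELL_PROB, None)
    return float(np.sum(table * np.log(probs)))


def polychoric_corr(table) -> float:
    """Two-step ML polychoric correlation from a two-way contingency table.

    Rows and columns index the ordered categories of the two variables.
    Thresholds are fixed from the margins; the latent correlation is found by
    bounded scalar maximisation of the log-likelihood on (-0.999, 0.999) with
    tolerance 1e-6.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    row_margin = table.sum(axis=1)
    col_margin = table.sum(axis=0)
    table = table[row_margin > 0][:, col_margin > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate table: need >= 2 observed categories per variable")
    tau1 = estimate_thresholds(table.sum(axis=1))
    tau2 = estimate_thresholds(table.sum(axis=0))

    result = optimize.minimize_scalar(
        lambda rho: -_table_loglik(rho, tau1, tau2, table),
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": _RHO_TOL},
    )
    if not result.success:
        raise RuntimeError(f"polychoric optimisation failed at rho={result.x:.6f}")
    return float(result.x)


def _crosstab(x: np.ndarray, y: np.ndarray, n_categories: int = 5) -> np.ndarray:
    table = np.zeros((n_categories, n_categories))
    for xi, yi in zip(x.astype(int), y.astype(int)):
        table[xi, yi] += 1
    return table


@dataclass
class PolychoricMatrix:
    """Pairwise polychoric correlations, repaired to PSD if necessary."""

    variable_ids: list[str]
    rho: np.ndarray
    smoothed: bool
    dropped: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.variable_ids, columns=self.variable_ids)


def _smooth_to_psd(rho: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    eigval, eigvec = np.linalg.eigh(rho)
    eigval = np.clip(eigval, floor, None)
    repaired = eigvec @ np.diag(eigval) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def polychoric_matrix(matrix: ScoreMatrix | pd.DataFrame) -> PolychoricMatrix:
    """Assemble the pairwise polychoric correlation matrix of a score table.

    Observations are the food systems (columns of the score matrix);
    variables are the indicators.  Degenerate variables (a single observed
    category) are dropped with a warning entry rather than aborting the run.
    A pairwise-assembled matrix need not be positive semi-definite; if any
    eigenvalue is negative it is repaired by eigenvalue clipping with
    rescaling to unit diagonal, and flagged ``smoothed``.
    """
    frame = matrix.scores if isinstance(matrix, ScoreMatrix) else matrix
    if frame.isna().any().any():
        raise ValueError("score table contains missing values; apply na_filter first")
    data = frame.to_numpy(dtype=float)

    keep, dropped = [], []
    for i, var in enumerate(frame.index):
        if np.unique(data[i]).size >= 2:
            keep.append(i)
        else:
            dropped.append(str(var))
    if len(keep) < 2:
        raise ValueError("need at least two non-degenerate variables")
    data = data[keep]
    ids = [str(frame.index[i]) for i in keep]

    p = len(ids)
    rho = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            table = _crosstab(data[i], data[j])
            rho[i, j] = rho[j, i] = polychoric_corr(table)

    eigvals = np.linalg.eigvalsh(rho)
    smoothed = bool(eigvals.min() < 0)
    if smoothed:
        rho = _smooth_to_psd(rho)
    return PolychoricMatrix(ids, rho, smoothed, dropped)


@dataclass
class PCAResult:
    """Eigenstructure of a correlation matrix with retention and influence lists."""

    variable_ids: list[str]
    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # variables x components
    variance_explained: np.ndarray  # per-component fraction of total variance
    retained: int
    influential: dict[int, list[str]]  # 1-based component -> ids, |loading| desc

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.variable_ids, columns=cols)


def pca_correlation(rho: np.ndarray, variable_ids: list[str] | None = None) -> PCAResult:
    """Principal components of a correlation matrix.

    Loadings are eigenvectors scaled by the square root of their eigenvalue;
    components are ordered by descending eigenvalue and each eigenvector's
    sign is fixed so its largest-magnitude loading is positive.  Retention
    and influence lists are left for the dedicated helpers; this result
    carries every component with ``retained`` initialised to 1.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(rho, rho.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    p = rho.shape[0]
    if variable_ids is None:
        variable_ids = [f"v{i + 1}" for i in range(p)]

    eigval, eigvec = np.linalg.eigh(rho)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(p):
        idx = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[idx, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    variance = eigval / np.trace(rho)
    return PCAResult(
        variable_ids=list(variable_ids),
        eigenvalues=eigval,
        loadings=loadings,
        variance_explained=variance,
        retained=1,
        influential={},
    )


def retain_components(eigenvalues, n_observations: int | None = None) -> int:
    """Kaiser criterion: count eigenvalues > 1, capped at n_observations - 1.

    At least one component is always retained.  The cap reflects the rank
    bound of data with few observations: m centred observations span at most
    m - 1 dimensions.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    count = int(np.sum(eigenvalues > 1.0))
    count = max(count, 1)
    if n_observations is not None:
        count = min(count, max(n_observations - 1, 1))
    return count


def influential_indicators(result: PCAResult, cutoff: float = 0.45) -> dict[int, list[str]]:
    """Per retained component, the variables with |loading| above the cutoff.

    Returned lists are sorted by |loading| descending; keys are 1-based
    component numbers.
    """
    if result.retained < 1:
        raise ValueError("at least one retained component required")
    lists: dict[int, list[str]] = {}
    for j in range(result.retained):
        col = result.loadings[:, j]
        idx = [i for i in range(len(col)) if abs(col[i]) > cutoff]
        idx.sort(key=lambda i: -abs(col[i]))
        lists[j + 1] = [result.variable_ids[i] for i in idx]
    return lists


def run_ordinal_pca(
    matrix: ScoreMatrix, cutoff: float = 0.45
) -> tuple[PCAResult, PolychoricMatrix, list[str]]:
    """Full ordinal PCA pipeline: N/A filter, polychoric matrix, PCA, influence.

    Returns the PCA result (with retention and influence lists filled in),
    the polychoric matrix, and the ids excluded by the N/A filter.
    """
    filtered, excluded = na_filter(matrix)
    poly = polychoric_matrix(filtered)
    result = pca_correlation(poly.rho, poly.variable_ids)
    result.retained = retain_components(
        result.eigenvalues, n_observations=len(filtered.food_systems)
    )
    result.influential = influential_indicators(result, cutoff=cutoff)
    return result, poly, excluded
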