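"""Polychoric correlation estimation and correlation-matrix PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foodsust.framework import ScoreMatrix
from foodsust.ordinal_pca import (
    bivariate_normal_cdf,
    estimate_thresholds,
    influential_indicators,
    na_filter,
    pca_correlation,
    polychoric_corr,
    polychoric_matrix,
    retain_components,
    run_ordinal_pca,
)
from foodsust.synthetic_data import LatentSpec, simulate_ordinal

QUARTILE_CUTS = np.array([-0.6744897501960817, 0.0, 0.6744897501960817])


def crosstab(x, y, k=5):
    table = np.zeros((k, k))
    for a, b in zip(x, y):
        table[int(a), int(b)] += 1
    return table


class TestBivariateNormalCdf:
    def test_against_scipy_mvn(self):
        rng = np.random.default_rng(2)
        for rho in (-0.95, -0.4, 0.2, 0.7, 0.99):
            mvn = stats.multivariate_normal(cov=[[1, rho], [rho, 1]])
            points = rng.normal(size=(40, 2)) * 1.5
            ours = bivariate_normal_cdf(points[:, 0], points[:, 1], rho)
            reference = mvn.cdf(points)
            assert np.allclose(ours, reference, atol=1e-7)

    def test_origin_closed_form(self):
        for rho in (-0.9, -0.3, 0.0, 0.5, 0.95):
            expected = 0.25 + np.arcsin(rho) / (2 * np.pi)
            assert bivariate_normal_cdf(0.0, 0.0, rho) == pytest.approx(expected, abs=1e-12)

    def test_infinite_bounds(self):
        assert bivariate_normal_cdf(np.inf, np.inf, 0.5) == 1.0
        assert bivariate_normal_cdf(-np.inf, 1.0, 0.5) == 0.0
        assert bivariate_normal_cdf(np.inf, 1.3, 0.5) == pytest.approx(stats.norm.cdf(1.3))


class TestThresholds:
    def test_balanced_binary(self):
        assert estimate_thresholds([50, 50]) == pytest.approx([0.0])

    def test_quartile_counts(self):
        tau = estimate_thresholds([25, 25, 25, 25])
        assert tau == pytest.approx([stats.norm.ppf(0.25), 0.0, stats.norm.ppf(0.75)])

    def test_skewed_binary(self):
        assert estimate_thresholds([10, 90]) == pytest.approx([stats.norm.ppf(0.1)])
        assert estimate_thresholds([10, 90])[0] == pytest.approx(-1.2816, abs=5e-5)

    def test_degenerate_variable_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_thresholds([0, 100, 0])
        with pytest.raises(ValueError):
            estimate_thresholds([0, 0])


class TestPolychoricCorr:
    def test_perfect_concordance_hits_boundary(self):
        x = np.array([0, 0, 1, 1, 2, 2, 3, 3, 4, 4] * 10)
        rho = polychoric_corr(crosstab(x, x))
        assert rho >= 0.99

    def test_independence_recovers_zero(self):
        margins = np.array([10, 20, 40, 20, 10], dtype=float)
        table = np.outer(margins, margins) / margins.sum()
        assert abs(polychoric_corr(table)) < 1e-3

    def test_latent_model_recovery(self):
        spec = LatentSpec(np.array([[1, 0.6], [0.6, 1]]), [QUARTILE_CUTS] * 2, n=2000)
        data = simulate_ordinal(spec, seed=42)
        rho = polychoric_corr(crosstab(data[:, 0], data[:, 1], k=4))
        assert rho == pytest.approx(0.6, abs=0.05)

    def test_antisymmetric_under_category_reversal(self):
        spec = LatentSpec(np.array([[1, 0.5], [0.5, 1]]), [QUARTILE_CUTS] * 2, n=800)
        data = simulate_ordinal(spec, seed=7)
        table = crosstab(data[:, 0], data[:, 1], k=4)
        assert polychoric_corr(table[::-1, :]) == pytest.approx(
            -polychoric_corr(table), abs=1e-4
        )

    def test_recovery_mean_absolute_error(self):
        # parameter recovery across the correlation range at moderate n
        errors = []
        seed = 0
        for true_rho in (-0.8, -0.4, 0.0, 0.4, 0.8):
            corr = np.array([[1, true_rho], [true_rho, 1]])
            for _ in range(40):
                data = simulate_ordinal(
                    LatentSpec(corr, [QUARTILE_CUTS] * 2, n=500), seed=seed
                )
                seed += 1
                table = crosstab(data[:, 0], data[:, 1], k=4)
                errors.append(abs(polychoric_corr(table) - true_rho))
        assert np.mean(errors) < 0.07

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            polychoric_corr(np.array([[5, 5]]))


class TestPolychoricMatrix:
    def test_identical_variables(self):
        frame = pd.DataFrame(
            [[0, 1, 2, 3, 4, 2], [0, 1, 2, 3, 4, 2]], index=["a", "b"],
            columns=list("uvwxyz"),
        )
        result = polychoric_matrix(ScoreMatrix(frame))
        assert result.rho[0, 1] >= 0.99

    def test_independent_variables_near_identity(self):
        spec = LatentSpec(np.eye(4), [QUARTILE_CUTS] * 4, n=3000)
        data = simulate_ordinal(spec, seed=3)
        frame = pd.DataFrame(data.T, index=[f"v{i}" for i in range(4)])
        result = polychoric_matrix(ScoreMatrix(frame))
        off = result.rho[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_six_observation_matrix_is_psd_after_smoothing(self):
        rng = np.random.default_rng(17)
        frame = pd.DataFrame(
            rng.integers(0, 5, size=(12, 6)).astype(float),
            index=[f"v{i}" for i in range(12)],
        )
        result = polychoric_matrix(ScoreMatrix(frame))
        eigvals = np.linalg.eigvalsh(result.rho)
        assert eigvals.min() >= -1e-10
        assert np.allclose(np.diag(result.rho), 1.0)

    def test_degenerate_variable_dropped(self):
        frame = pd.DataFrame(
            [[2, 2, 2, 2, 2, 2], [0, 1, 2, 3, 4, 2], [4, 3, 2, 1, 0, 2]],
            index=["flat", "up", "down"],
        )
        result = polychoric_matrix(ScoreMatrix(frame))
        assert result.dropped == ["flat"]
        assert result.variable_ids == ["up", "down"]


class TestNaFilter:
    def test_complete_matrix_unchanged(self, full_matrix):
        filtered, excluded = na_filter(full_matrix)
        assert excluded == []
        assert filtered.scores.equals(full_matrix.scores)

    def test_single_na_cell_excludes_exactly_that_indicator(self, full_matrix):
        matrix = full_matrix.copy()
        matrix.scores.iloc[10, 2] = np.nan
        filtered, excluded = na_filter(matrix)
        assert excluded == [full_matrix.indicator_ids[10]]
        assert len(filtered.indicator_ids) == len(full_matrix.indicator_ids) - 1

    def test_all_missing_rejected(self):
        m = ScoreMatrix(pd.DataFrame({"S1": [np.nan], "S2": [1.0]}, index=["a"]))
        with pytest.raises(ValueError):
            na_filter(m)


class TestPcaCorrelation:
    def test_identity_matrix(self):
        result = pca_correlation(np.eye(3))
        assert result.eigenvalues == pytest.approx([1, 1, 1])
        assert result.variance_explained == pytest.approx([1 / 3] * 3)

    def test_two_by_two_closed_form(self):
        rho = 0.8
        result = pca_correlation(np.array([[1, rho], [rho, 1]]))
        assert result.eigenvalues == pytest.approx([1 + rho, 1 - rho])

    def test_spectral_reconstruction(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            raw = rng.normal(size=(6, 6))
            cov = raw @ raw.T + 1e-3 * np.eye(6)
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            result = pca_correlation(corr)
            recon = sum(
                lam * np.outer(v, v)
                for lam, v in zip(
                    result.eigenvalues,
                    (result.loadings / np.sqrt(result.eigenvalues)).T,
                )
            )
            assert np.abs(recon - corr).max() < 1e-8
            assert result.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)

    def test_sign_convention(self):
        result = pca_correlation(np.array([[1, -0.6], [-0.6, 1]]))
        for j in range(2):
            col = result.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pca_correlation(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestRetention:
    @pytest.mark.parametrize(
        "eigenvalues, n_obs, expected",
        [
            ([3.0, 1.5, 0.9, 0.4], None, 2),
            ([0.9, 0.8], None, 1),  # floor of one component
            ([3, 2, 1.5, 1.2, 1.1, 0.2], 6, 5),  # capped at n - 1
        ],
    )
    def test_kaiser_with_cap(self, eigenvalues, n_obs, expected):
        assert retain_components(eigenvalues, n_obs) == expected


class TestInfluence:
    def test_absolute_value_threshold(self):
        result = pca_correlation(np.eye(3))
        result.retained = 1
        result.loadings = np.array([[0.5], [0.3], [-0.6]])
        result.variable_ids = ["a", "b", "c"]
        lists = influential_indicators(result, cutoff=0.45)
        assert lists[1] == ["c", "a"]  # sorted by |loading| descending

    def test_impossible_cutoff_empty(self):
        result = pca_correlation(np.eye(3))
        result.retained = 2
        assert all(not v for v in influential_indicators(result, cutoff=1.1).values())


class TestPipeline:
    def test_six_system_pipeline_rank_bound(self, full_matrix):
        result, poly, excluded = run_ordinal_pca(full_matrix)
        assert excluded == []
        assert 1 <= result.retained <= 5  # six observations span at most 5 dimensions
        assert result.variance_explained[: result.retained].sum() <= 1 + 1e-9
        assert result.eigenvalues.sum() == pytest.approx(len(result.variable_ids), abs=1e-8)
        for ids in result.influential.values():
            assert all(i in result.variable_ids for i in ids)
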