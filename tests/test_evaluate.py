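import numpy as np
import pytest

from poolcs import (
    cell_correlation_matrix,
    cell_correlations,
    detection_sensitivity,
    evaluate_reconstruction,
    gene_correlation_profile,
    library_savings,
)


class TestCellCorrelations:
    def test_self_correlation_is_one(self, small_scep):
        rho_c, rho = cell_correlations(small_scep, small_scep)
        np.testing.assert_allclose(rho_c, 1.0, atol=1e-12)
        assert rho == pytest.approx(1.0)

    def test_affine_invariance(self, small_scep):
        shifted = 2.0 * small_scep.values + 7.0
        rho_c, rho = cell_correlations(small_scep, shifted)
        np.testing.assert_allclose(rho_c, 1.0, atol=1e-10)

    def test_matches_textbook_formula(self):
        X = np.array([[1.0, 2.0, 4.0], [0.0, 1.0, 0.0], [5.0, 5.0, 2.0]])
        Xh = np.array([[1.5, 1.0, 3.0], [0.5, 0.5, 1.0], [4.0, 6.0, 1.0]])
        rho_c, _ = cell_correlations(X, Xh)
        for i in range(3):
            x, y = X[i], Xh[i]
            num = ((x - x.mean()) * (y - y.mean())).sum()
            den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            assert rho_c[i] == pytest.approx(num / den, abs=1e-12)

    def test_constant_row_excluded_from_mean(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        Xh = X.copy()
        rho_c, rho = cell_correlations(X, Xh)
        assert np.isnan(rho_c[1])
        assert rho == pytest.approx(1.0)  # mean over the defined cell only

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cell_correlations(np.ones((2, 3)), np.ones((3, 2)))

    def test_mean_equals_mean_of_finite_entries(self, small_scep, rng):
        noisy = small_scep.values + rng.normal(0, 50, small_scep.shape)
        noisy = np.clip(noisy, 0, None)
        rho_c, rho = cell_correlations(small_scep, noisy)
        assert rho == pytest.approx(np.nanmean(rho_c), abs=0)

    def test_matrix_diagonal_equals_per_cell(self, small_scep, rng):
        noisy = np.clip(
            small_scep.values + rng.normal(0, 20, small_scep.shape), 0, None
        )
        rho_c, _ = cell_correlations(small_scep, noisy)
        corr = cell_correlation_matrix(small_scep, noisy)
        np.testing.assert_allclose(np.diag(corr), rho_c, atol=1e-12)


class TestDetectionSensitivity:
    def test_perfect_recovery(self, small_scep):
        res = detection_sensitivity(small_scep, small_scep)
        assert res.detection_fraction == pytest.approx(1.0)

    def test_one_lost_gene_of_four(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0]])
        Xh = np.array([[1.0, 0.0, 3.0, 4.0]])
        res = detection_sensitivity(X, Xh)
        assert res.detected_original == 4
        assert res.detected_inferred == 3
        assert res.detection_fraction == pytest.approx(0.75)

    def test_high_expression_stratum(self):
        # two lost genes; only one has original total > 1
        X = np.array([[0.5, 3.0, 2.0]])
        Xh = np.array([[0.0, 0.0, 2.0]])
        res = detection_sensitivity(X, Xh, high_expr_threshold=1.0)
        assert res.lost_high_expression == 1

    def test_monotone_in_detect_tol(self, small_scep):
        counts = [
            detection_sensitivity(small_scep, small_scep, detect_tol=tol)
            .detected_original
            for tol in (0.0, 0.001, 1.0, 100.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestGeneCorrelationProfile:
    def test_perfect_recovery_all_bins_one(self, small_scep):
        per_gene, summary = gene_correlation_profile(small_scep, small_scep)
        defined = per_gene.dropna(subset=["correlation"])
        np.testing.assert_allclose(defined["correlation"], 1.0, atol=1e-12)
        np.testing.assert_allclose(summary["median"], 1.0, atol=1e-12)

    def test_bins_match_brute_force_quantile_split(self, rng):
        X = rng.random((10, 5)) * 10
        Xh = np.clip(X + rng.normal(0, 1, X.shape), 0, None)
        per_gene, _ = gene_correlation_profile(
            X, Xh, ranking="total_expression", n_bins=5
        )
        order = np.argsort(X.sum(axis=0), kind="stable")
        expected_bins = np.empty(5, dtype=int)
        expected_bins[order] = np.arange(5)  # 5 genes, 5 bins: rank = bin
        np.testing.assert_array_equal(per_gene["bin"].to_numpy(), expected_bins)

    def test_sparsity_ranking_uses_expressing_cells(self, rng):
        X = np.zeros((8, 4))
        X[:1, 0] = 5.0  # sparsest
        X[:3, 1] = 5.0
        X[:5, 2] = 5.0
        X[:8, 3] = 5.0  # densest
        Xh = X + rng.random(X.shape) * 0.1
        per_gene, _ = gene_correlation_profile(
            X, Xh, ranking="sparsity_level", n_bins=4
        )
        assert per_gene.sort_values("bin")["expressing_cells"].is_monotonic_increasing

    def test_constant_genes_excluded(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0]])  # gene 0 constant
        per_gene, _ = gene_correlation_profile(X, X)
        assert np.isnan(per_gene["correlation"][0])
        assert per_gene["correlation"][1] == pytest.approx(1.0)


class TestLibrarySavings:
    @pytest.mark.parametrize(
        "cells,pools,saved,pct",
        [(54, 28, 26, 48.15), (64, 35, 29, 45.31), (10, 10, 0, 0.0)],
    )
    def test_savings_accounting(self, cells, pools, saved, pct):
        res = library_savings(cells, pools)
        assert res.libraries_saved == saved
        assert res.savings_fraction_pct == pytest.approx(pct)

    def test_more_pools_than_cells_saves_nothing(self):
        res = library_savings(10, 40)
        assert res.libraries_saved == 0
        assert res.savings_fraction_pct == 0.0


class TestEvaluationReport:
    def test_report_bundle_consistency(self, small_scep, rng):
        noisy = np.clip(
            small_scep.values + rng.normal(0, 30, small_scep.shape), 0, None
        )
        report = evaluate_reconstruction(small_scep, noisy, n_pools=35)
        assert report.mean_rho == pytest.approx(np.nanmean(report.per_cell_rho))
        np.testing.assert_allclose(
            np.diag(report.cell_by_cell_corr), report.per_cell_rho, atol=1e-12
        )
        assert report.savings.libraries_saved == 64 - 35
        scalars = report.scalars()
        assert 0 <= scalars["detection_fraction"] <= 1.5
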