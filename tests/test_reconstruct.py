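import numpy as np
import pytest
from scipy.optimize import minimize

from poolcs import (
    BasisPursuitError,
    BasisPursuitReconstructor,
    RidgeReconstructor,
    SolverConfig,
    basis_pursuit_solve,
    block_reconstruct,
    cell_correlations,
    generate_measurement_matrix,
    measure,
    partition_cells,
    ridge_solve,
    threshold_expression,
)
from poolcs.compress import PoolMatrix


from _oracles import bp_oracle_sparse


class TestRidge:
    def test_identity_closed_form(self):
        M = np.eye(2)
        Y = np.array([[2.0], [3.0]])
        X = ridge_solve(M, Y, lambda_=0.01)
        np.testing.assert_allclose(
            X.values[:, 0], [2 / 1.01, 3 / 1.01], atol=1e-12
        )

    def test_small_lambda_approaches_inverse(self, rng):
        M = rng.random((5, 5)) + np.eye(5)  # well-conditioned square
        y = rng.random((5, 1))
        X = ridge_solve(M, y, lambda_=1e-12)
        np.testing.assert_allclose(X.values[:, 0], np.linalg.solve(M, y[:, 0]),
                                   atol=1e-8)

    def test_matches_direct_formula(self, rng):
        """Estimator output equals direct evaluation of
        (lambda I + M'M)^-1 M'y per column to 1e-10."""
        for _ in range(20):
            M = rng.integers(0, 2, (6, 10)).astype(float)
            Y = rng.random((6, 3)) * 100
            lam = 0.01
            X = ridge_solve(M, Y, lambda_=lam)
            direct = np.linalg.solve(lam * np.eye(10) + M.T @ M, M.T @ Y)
            np.testing.assert_allclose(X.values, direct, atol=1e-10)

    def test_matches_iterative_minimizer(self, rng):
        """Closed form agrees with numerical minimization of
        ||Mx-y||^2 + lambda ||x||^2 within 1e-6."""
        lam = 0.01
        for _ in range(5):
            M = rng.integers(0, 2, (6, 10)).astype(float)
            y = rng.random(6) * 50

            def objective(x):
                r = M @ x - y
                return r @ r + lam * (x @ x)

            def gradient(x):
                return 2.0 * (M.T @ (M @ x - y)) + 2.0 * lam * x

            x_closed = ridge_solve(M, y[:, None], lambda_=lam).values[:, 0]
            res = minimize(objective, np.zeros(10), jac=gradient,
                           method="L-BFGS-B",
                           options={"gtol": 1e-12, "ftol": 1e-16})
            assert np.abs(x_closed - res.x).max() < 1e-6

    def test_requires_fit_before_transform(self):
        with pytest.raises(RuntimeError, match="fit"):
            RidgeReconstructor().transform(np.ones((3, 2)))

    def test_get_set_params(self):
        est = RidgeReconstructor(alpha=0.5)
        assert est.get_params() == {"alpha": 0.5}
        est.set_params(alpha=0.125)
        assert est.alpha == 0.125


class TestBasisPursuit:
    def test_zero_measurements_give_zero(self, small_design):
        Y = np.zeros((35, 4))
        X = basis_pursuit_solve(small_design, Y)
        assert (X.values == 0).all()

    def test_minimal_l1_on_feasible_line(self):
        """For M=[[1,1,0],[0,1,1]], y=[1,1] the feasible set is the line
        x=(a, 1-a, a); the l1 minimum is uniquely x=[0,1,0]."""
        M = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        Y = np.array([[1.0], [1.0]])
        X = basis_pursuit_solve(M, Y)
        np.testing.assert_allclose(X.values[:, 0], [0.0, 1.0, 0.0], atol=1e-7)

    def test_one_sparse_exact_recovery_all_positions(self):
        """Every 1-sparse signal is recovered exactly on a Bernoulli
        design with distinct, nonzero columns; checked against support
        enumeration."""
        M = generate_measurement_matrix(6, 8, 0.5, seed=12).values
        assert np.unique(M, axis=1).shape[1] == 8  # identifiable columns
        for pos in range(8):
            x_true = np.zeros(8)
            x_true[pos] = 1.0
            y = M @ x_true
            x_hat = basis_pursuit_solve(M, y[:, None]).values[:, 0]
            x_oracle = bp_oracle_sparse(M, y, k_max=1)
            np.testing.assert_allclose(x_hat, x_true, atol=1e-7)
            np.testing.assert_allclose(x_oracle, x_true, atol=1e-9)

    def test_square_full_rank_recovers_dense_signal(self, rng):
        """With as many pools as cells and an invertible design the tube
        constraint pins down the exact signal, sparse or not."""
        while True:
            M = (rng.random((10, 10)) < 0.5).astype(float)
            if np.linalg.matrix_rank(M) == 10:
                break
        X_true = rng.random((10, 3)) * 20
        Y = M @ X_true
        X_hat = basis_pursuit_solve(M, Y)
        np.testing.assert_allclose(X_hat.values, X_true, atol=1e-4)

    def test_infeasible_measurements_raise_with_gene_label(self):
        M = np.array([[1.0, 1.0], [1.0, 1.0]])  # rank 1
        Y = PoolMatrix(values=np.array([[1.0], [2.0]]), gene_labels=["GENE7"])
        est = BasisPursuitReconstructor().fit(M)
        with pytest.raises(BasisPursuitError, match="GENE7") as err:
            est.transform(Y)
        assert err.value.genes == ["GENE7"]

    def test_nonneg_flag_restricts_solution(self):
        M = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        Y = np.array([[1.0], [1.0]])
        config = SolverConfig(method="basis_pursuit", nonneg=True)
        X = basis_pursuit_solve(M, Y, config)
        assert (X.values >= -1e-12).all()

    def test_worker_count_does_not_change_result(self, small_design, small_scep):
        Y = measure(small_design, small_scep)
        Y_sub = PoolMatrix(values=Y.values[:, :40])
        a = BasisPursuitReconstructor(n_workers=1).fit(small_design.values)
        b = BasisPursuitReconstructor(n_workers=2).fit(small_design.values)
        np.testing.assert_array_equal(
            a.transform(Y_sub).values, b.transform(Y_sub).values
        )


class TestPartitionCells:
    def test_ten_block_layout(self):
        p = partition_cells(5063, 500, 1600)
        assert p.block_sizes == (500,) * 9 + (563,)
        assert p.pools_per_block == (158,) * 9 + (178,)

    def test_ninety_one_block_layout(self):
        p = partition_cells(45423, 500, 22700)
        assert len(p.block_sizes) == 91
        assert p.block_sizes == (500,) * 90 + (423,)
        assert p.pools_per_block == (250,) * 90 + (200,)

    def test_block_size_exceeding_cells_gives_single_block(self):
        p = partition_cells(10, 20, 5)
        assert p.block_sizes == (10,)
        assert p.pools_per_block == (5,)

    def test_totals_conserved(self):
        for args in [(5063, 500, 1600), (45423, 500, 22700), (997, 100, 450)]:
            p = partition_cells(*args)
            assert p.n_cells == args[0]
            assert p.n_pools == args[2]

    def test_too_few_pools_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            partition_cells(1000, 100, 5)


class TestBlockReconstruct:
    def test_single_block_matches_manual_pipeline(self, small_scep):
        from poolcs.reconstruct import _block_seeds

        config = SolverConfig(method="ridge")
        p = partition_cells(64, 100, 35)
        blocked = block_reconstruct(small_scep, p, config, seed=5)
        d_seed, t_seed = _block_seeds(5, 0)
        design = generate_measurement_matrix(35, 64, 0.5, seed=d_seed)
        Y = measure(design, small_scep)
        manual = ridge_solve(design.values, Y)
        np.testing.assert_array_equal(blocked.values, manual.values)

    def test_serial_equals_parallel(self, small_scep):
        config = SolverConfig(method="ridge")
        p = partition_cells(64, 16, 32)
        serial = block_reconstruct(small_scep, p, config, seed=3, n_workers=1)
        parallel = block_reconstruct(small_scep, p, config, seed=3, n_workers=3)
        np.testing.assert_array_equal(serial.values, parallel.values)

    def test_blocks_are_independent(self, small_scep):
        """Each block's recovery equals decoding that block alone."""
        config = SolverConfig(method="ridge")
        p = partition_cells(64, 32, 30)
        full = block_reconstruct(small_scep, p, config, seed=11)

        half = small_scep.values[:32]
        p_half = partition_cells(32, 32, p.pools_per_block[0])
        from poolcs.reconstruct import _block_seeds

        d_seed, _ = _block_seeds(11, 0)
        design = generate_measurement_matrix(
            p.pools_per_block[0], 32, 0.5, seed=d_seed
        )
        alone = ridge_solve(design.values, design.values @ half)
        np.testing.assert_allclose(full.values[:32], alone.values, atol=1e-12)

    def test_blocked_close_to_unblocked_quality(self):
        """Partitioning 256 synthetic cells into 4 blocks costs little
        accuracy at a matched pools-per-cell ratio."""
        from poolcs import SyntheticProfileSpec, simulate_scep

        X = simulate_scep(
            SyntheticProfileSpec(n_cells=256, n_genes=400, n_types=4, seed=21)
        )
        config = SolverConfig(method="ridge")
        blocked = block_reconstruct(
            X, partition_cells(256, 64, 144), config, seed=2
        )
        unblocked = block_reconstruct(
            X, partition_cells(256, 300, 144), config, seed=2
        )
        _, rho_blocked = cell_correlations(X, blocked)
        _, rho_unblocked = cell_correlations(X, unblocked)
        assert abs(rho_blocked - rho_unblocked) < 0.05

    def test_partition_matrix_mismatch(self, small_scep):
        config = SolverConfig()
        with pytest.raises(ValueError, match="cells"):
            block_reconstruct(
                small_scep, partition_cells(100, 50, 20), config, seed=0
            )


class TestThresholdExpression:
    def test_floor_five(self):
        X = np.array([[4.9, 5.0, 7.2]])
        out, _ = threshold_expression(X, detect_tol=0.0, floor_value=5.0)
        np.testing.assert_array_equal(out.values, [[0.0, 5.0, 7.2]])

    def test_disabled_thresholds_are_identity(self):
        X = np.array([[0.5, 0.0], [1.0, 2.0]])
        out, undetected = threshold_expression(X, detect_tol=0.0, floor_value=0.0)
        np.testing.assert_array_equal(out.values, X)
        assert not undetected.any()

    def test_undetected_gene_flagged_and_droppable(self):
        X = np.array([[0.0006, 3.0], [0.0005, 1.0]])  # total 0.0011 detected
        out, undetected = threshold_expression(X, detect_tol=0.001)
        np.testing.assert_array_equal(undetected, [False, False])
        X2 = np.array([[0.0004, 3.0], [0.0005, 1.0]])
        # total 0.0009 < 0.001 -> flagged
        out2, undetected2 = threshold_expression(
            X2, detect_tol=0.001, drop_undetected=True
        )
        np.testing.assert_array_equal(undetected2, [True, False])
        assert out2.n_genes == 1

    def test_negative_values_clamped(self):
        X = np.array([[-0.5, 2.0]])
        out, _ = threshold_expression(X, detect_tol=0.0, floor_value=0.0)
        np.testing.assert_array_equal(out.values, [[0.0, 2.0]])


class TestLambdaSearch:
    def test_grid_scores_each_lambda(self, small_design, small_scep):
        from poolcs import measure, ridge_lambda_search

        Y = measure(small_design, small_scep)
        grid = [0.001, 0.01, 1000.0]
        results = ridge_lambda_search(small_design, Y, small_scep, grid)
        assert [lam for lam, _ in results] == grid
        rhos = dict(results)
        # an absurdly strong penalty must hurt relative to the default
        assert rhos[0.01] > rhos[1000.0]
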