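"""Design matrix, subset least squares, Monte-Carlo TFCV/TFL accumulation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dhstf.errors import AlignmentError, EmptyInputError, ParameterError
from dhstf.model import (
    DesignMatrix,
    TFScoreTable,
    compare_thresholds,
    design_matrix,
    fit_subset,
    mc_standard_errors,
    rank_tfs,
    run_exhaustive,
    run_monte_carlo,
)
from dhstf.pwm import AffinityMatrix
from dhstf.regions import IndicatorMatrix
from dhstf.synthetic import toy_matrices


def normal_equations_oracle(A_s, Z):
    """Independent pseudoinverse solution and residual."""
    x = np.linalg.pinv(A_s) @ Z
    r = Z - A_s @ x
    return x, float(r @ r)


class TestDesignMatrix:
    def test_identity_like_product(self):
        C = IndicatorMatrix(["g1", "g2"], ["d1", "d2"],
                            np.array([[1, 0], [0, 1]], dtype=np.uint8))
        D = AffinityMatrix(["d1", "d2"], ["p1", "p2"],
                           np.array([[5.0, 0], [0, 3.0]]), np.array([5.0, 3.0]))
        A = design_matrix(C, D)
        np.testing.assert_array_equal(A.values, [[5.0, 0], [0, 3.0]])
        assert A.gene_ids == ["g1", "g2"] and A.pwm_ids == ["p1", "p2"]

    def test_zero_indicator_gives_zero_design(self):
        C = IndicatorMatrix(["g1"], ["d1", "d2"], np.zeros((1, 2), dtype=np.uint8))
        D = AffinityMatrix(["d1", "d2"], ["p1"], np.ones((2, 1)), np.ones(1))
        assert not design_matrix(C, D).values.any()

    def test_random_product_matches_triple_loop(self):
        rng = np.random.default_rng(0)
        Cv = (rng.random((10, 20)) < 0.3).astype(np.uint8)
        Dv = rng.random((20, 15)) * 5
        C = IndicatorMatrix([f"g{i}" for i in range(10)],
                            [f"d{m}" for m in range(20)], Cv)
        D = AffinityMatrix([f"d{m}" for m in range(20)],
                           [f"p{j}" for j in range(15)], Dv, np.zeros(15))
        A = design_matrix(C, D)
        oracle = np.zeros((10, 15))
        for k in range(10):
            for i in range(15):
                for m in range(20):
                    oracle[k, i] += Cv[k, m] * Dv[m, i]
        np.testing.assert_allclose(A.values, oracle, rtol=1e-12)

    def test_dhs_id_mismatch_raises_with_position(self):
        C = IndicatorMatrix(["g1"], ["d1", "dX"], np.ones((1, 2), dtype=np.uint8))
        D = AffinityMatrix(["d1", "d2"], ["p1"], np.ones((2, 1)), np.ones(1))
        with pytest.raises(AlignmentError, match="position 1"):
            design_matrix(C, D)


class TestFitSubset:
    def test_exact_model_recovers_x(self):
        rng = np.random.default_rng(1)
        A = rng.normal(0, 2, (30, 8))
        x_true = np.array([1.5, -0.5, 2.0])
        subset = [0, 3, 6]
        Z = A[:, subset] @ x_true
        fit = fit_subset(A, Z, subset)
        assert fit.err <= 1e-18 * float(Z @ Z)
        np.testing.assert_allclose(fit.x, x_true, rtol=1e-9)

    def test_all_zero_design_returns_zero_x_full_err(self):
        A = np.zeros((10, 4))
        Z = np.arange(10.0)
        fit = fit_subset(A, Z, [0, 2])
        np.testing.assert_array_equal(fit.x, [0.0, 0.0])
        assert fit.err == pytest.approx(float(Z @ Z))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            A = rng.normal(0, 3, (30, 5))
            Z = rng.normal(0, 2, 30)
            fit = fit_subset(A, Z, list(range(5)))
            _, err_oracle = normal_equations_oracle(A, Z)
            assert fit.err == pytest.approx(err_oracle, rel=1e-8)

    def test_rank_deficient_minimum_norm(self):
        rng = np.random.default_rng(3)
        col = rng.normal(0, 1, 20)
        A = np.column_stack([col, col])  # perfectly collinear
        Z = 3.0 * col
        fit = fit_subset(A, Z, [0, 1])
        x_oracle, err_oracle = normal_equations_oracle(A, Z)
        assert fit.err == pytest.approx(err_oracle, abs=1e-18)
        np.testing.assert_allclose(fit.x, x_oracle, rtol=1e-8)  # [1.5, 1.5]

    def test_duplicate_subset_rejected(self):
        with pytest.raises(ParameterError):
            fit_subset(np.ones((4, 3)), np.ones(4), [1, 1])


class TestMonteCarlo:
    def test_single_iteration_unfolds_definition(self):
        C, D, Z, _ = toy_matrices(seed=5)
        A = design_matrix(C, D)
        table = run_monte_carlo(A, Z, n_t=3, n_iter=1, seed=99)
        selected = np.flatnonzero(table.n_selected)
        assert selected.size == 3
        fit = fit_subset(A, Z, list(selected))
        w = 1.0 / max(fit.err, 1e-12) ** 2
        np.testing.assert_allclose(table.tfcv[selected], w, rtol=1e-9)
        np.testing.assert_allclose(
            np.sort(table.tfl[selected]), np.sort(fit.x), rtol=1e-9
        )
        assert not table.tfcv[~np.isin(np.arange(len(table.tfcv)), selected)].any()

    def test_selection_conservation(self):
        C, D, Z, _ = toy_matrices(seed=6)
        A = design_matrix(C, D)
        table = run_monte_carlo(A, Z, n_t=4, n_iter=500, seed=1)
        assert int(table.n_selected.sum()) == 4 * 500

    def test_identical_increment_within_iteration(self):
        # with one iteration, all selected PWMs share the same TFCV increment
        C, D, Z, _ = toy_matrices(seed=7)
        A = design_matrix(C, D)
        table = run_monte_carlo(A, Z, n_t=3, n_iter=1, seed=3)
        vals = table.tfcv[table.tfcv > 0]
        assert np.ptp(vals) <= 1e-12 * vals.max()

    def test_deterministic_for_fixed_seed(self):
        C, D, Z, _ = toy_matrices(seed=8)
        A = design_matrix(C, D)
        t1 = run_monte_carlo(A, Z, n_t=3, n_iter=2000, seed=42)
        t2 = run_monte_carlo(A, Z, n_t=3, n_iter=2000, seed=42)
        np.testing.assert_array_equal(t1.tfcv, t2.tfcv)
        np.testing.assert_array_equal(t1.tfl, t2.tfl)
        np.testing.assert_array_equal(t1.n_selected, t2.n_selected)

    def test_chunking_does_not_change_results(self):
        C, D, Z, _ = toy_matrices(seed=9)
        A = design_matrix(C, D)
        t1 = run_monte_carlo(A, Z, n_t=3, n_iter=1000, seed=5, chunk_size=64)
        t2 = run_monte_carlo(A, Z, n_t=3, n_iter=1000, seed=5, chunk_size=1000)
        np.testing.assert_array_equal(t1.tfcv, t2.tfcv)

    def test_mc_matches_fit_subset_per_subset(self):
        """The batched normal-equations path agrees with the direct solver."""
        C, D, Z, _ = toy_matrices(n_pwms=6, seed=10)
        A = design_matrix(C, D)
        table = run_monte_carlo(A, Z, n_t=6, n_iter=1, seed=0)  # forced subset
        fit = fit_subset(A, Z, list(range(6)))
        w = 1.0 / max(fit.err, 1e-12) ** 2
        np.testing.assert_allclose(table.tfcv, w, rtol=1e-8)

    def test_nt_larger_than_columns_rejected(self):
        C, D, Z, _ = toy_matrices(n_pwms=4, seed=11)
        A = design_matrix(C, D)
        with pytest.raises(ParameterError):
            run_monte_carlo(A, Z, n_t=5, n_iter=10, seed=0)

    def test_exhaustive_agreement_within_three_se(self):
        C, D, Z, _ = toy_matrices(n_genes=20, n_dhs=25, n_pwms=6, seed=12)
        A = design_matrix(C, D)
        n_t, n_iter = 2, 30_000
        exhaustive = run_exhaustive(A, Z, n_t=n_t)
        n_subsets = exhaustive.n_iterations
        assert n_subsets == 15
        mc = run_monte_carlo(A, Z, n_t=n_t, n_iter=n_iter, seed=21)
        se = mc_standard_errors(A, Z, n_t, n_iter)
        expected = exhaustive.tfcv * n_iter / n_subsets
        assert np.all(np.abs(mc.tfcv - expected) <= 3 * se + 1e-12)

    def test_exhaustive_counts(self):
        C, D, Z, _ = toy_matrices(n_pwms=6, seed=13)
        A = design_matrix(C, D)
        table = run_exhaustive(A, Z, n_t=2)
        # each PWM appears in C(5,1)=5 of the 15 subsets
        np.testing.assert_array_equal(table.n_selected, np.full(6, 5))


class TestRanking:
    def make_table(self, tfcv, ids=None):
        n = len(tfcv)
        ids = ids or [f"M{i}" for i in range(n)]
        return TFScoreTable(ids, np.asarray(tfcv, float), np.zeros(n),
                            np.ones(n, dtype=np.int64), 1)

    def test_descending_order(self):
        table = self.make_table([3.0, 5.0, 1.0], ids=["a", "b", "c"])
        ranked = rank_tfs(table, top_n=2)
        assert list(ranked["pwm_id"]) == ["b", "a"]

    def test_ties_break_lexicographically(self):
        table = self.make_table([1.0, 1.0, 1.0], ids=["c", "a", "b"])
        ranked = rank_tfs(table, top_n=3)
        assert list(ranked["pwm_id"]) == ["a", "b", "c"]

    def test_top_n_beyond_size_returns_full_ranking(self, caplog):
        table = self.make_table([2.0, 1.0])
        with caplog.at_level("WARNING"):
            ranked = rank_tfs(table, top_n=10)
        assert len(ranked) == 2
        assert "full ranking" in caplog.text


class TestCompareThresholds:
    def make_table(self, tfcv):
        n = len(tfcv)
        return TFScoreTable([f"M{i}" for i in range(n)], np.asarray(tfcv, float),
                            np.zeros(n), np.ones(n, dtype=np.int64), 1)

    def test_self_correlation_is_one(self):
        t = self.make_table([1.0, 3.0, 2.0])
        corr = compare_thresholds([t, t])
        np.testing.assert_allclose(corr.to_numpy(), np.ones((2, 2)))

    def test_affine_invariance(self):
        t1 = self.make_table([1.0, 3.0, 2.0, 5.0])
        t2 = self.make_table(2.0 * np.array([1.0, 3.0, 2.0, 5.0]) + 3.0)
        corr = compare_thresholds([t1, t2])
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(14)
        a, b = rng.random(100), rng.random(100)
        corr = compare_thresholds([self.make_table(a), self.make_table(b)])
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert corr.iloc[0, 1] == pytest.approx(num / den, rel=1e-12)

    def test_constant_vector_reported_missing(self):
        t1 = self.make_table([1.0, 1.0, 1.0])
        t2 = self.make_table([1.0, 2.0, 3.0])
        corr = compare_thresholds([t1, t2])
        assert np.isnan(corr.iloc[0, 1])
        assert corr.iloc[0, 0] == 1.0

    def test_mismatched_orderings_rejected(self):
        t1 = self.make_table([1.0, 2.0])
        t2 = TFScoreTable(["X", "Y"], np.array([1.0, 2.0]), np.zeros(2),
                          np.ones(2, dtype=np.int64), 1)
        with pytest.raises(AlignmentError):
            compare_thresholds([t1, t2])

    def test_fewer_than_two_tables_rejected(self):
        with pytest.raises(EmptyInputError):
            compare_thresholds([self.make_table([1.0, 2.0])])


def test_score_table_tsv_roundtrip(tmp_path):
    C, D, Z, _ = toy_matrices(seed=15)
    A = design_matrix(C, D)
    table = run_monte_carlo(A, Z, n_t=3, n_iter=200, seed=2)
    table.write(tmp_path / "scores.tsv")
    again = TFScoreTable.read(tmp_path / "scores.tsv")
    assert again.pwm_ids == table.pwm_ids
    np.testing.assert_allclose(again.tfcv, table.tfcv, rtol=1e-10)
    np.testing.assert_allclose(again.tfl, table.tfl, rtol=1e-10)
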