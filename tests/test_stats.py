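import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from convar import (
    MultipleAlignment,
    UndefinedStatisticError,
    bh_fdr,
    blosum62_pca,
    bonferroni_outlier_test,
    fit_linear_regression,
    hypergeometric_overlap,
    spearman_rho,
)

from _oracles import hypergeom_upper_tail


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = spearman_rho(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)
        # and against the reference implementation, including ties
        xt = np.round(x)  # force ties
        ref_rho, ref_p = sps.spearmanr(xt, y)
        got = spearman_rho(xt, y)
        assert got.rho == pytest.approx(ref_rho, abs=1e-12)
        assert got.p_value == pytest.approx(ref_p, rel=1e-9)

    def test_symmetry(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert spearman_rho(x, y).rho == pytest.approx(spearman_rho(y, x).rho)

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=30)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman_rho(x, y).rho
        assert spearman_rho(np.exp(x), y).rho == pytest.approx(base)
        assert spearman_rho(x, y**3).rho == pytest.approx(base)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1], [1, 2, 3])


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        fit = fit_linear_regression(x, y)
        X = np.column_stack([np.ones(30), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        r2 = 1 - np.sum((y - X @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
        assert fit.adjusted_r2 == pytest.approx(1 - (1 - r2) * 29 / 28, abs=1e-10)

    def test_residuals_sum_to_zero(self, rng):
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        fit = fit_linear_regression(x, y)
        assert abs(fit.residuals.sum()) < 1e-10

    def test_constant_x_rejected(self):
        with pytest.raises(Exception):
            fit_linear_regression([1, 1, 1, 1], [1, 2, 3, 4])


class TestOutlierTest:
    def test_planted_gross_outlier_found(self, rng):
        x = np.arange(20.0)
        y = 3 * x + 2 + rng.normal(scale=0.1, size=20)
        y[7] += 50 * 0.1  # 50 sigma displacement
        fit = fit_linear_regression(x, y)
        rep = bonferroni_outlier_test(fit)
        assert rep.indices[0] == 7
        assert rep.adjusted_p[0] < 0.05

    def test_noise_free_line_has_no_outliers(self):
        x = np.arange(10.0)
        fit = fit_linear_regression(x, 2 * x)
        rep = bonferroni_outlier_test(fit)
        assert rep.indices == []

    def test_cap_at_n_max(self, rng):
        # five strong alternating-sign outliers; each survives the sigma
        # inflation the others cause, but only n_max are reported
        x = np.arange(100.0)
        y = x + rng.normal(scale=0.01, size=100)
        for sign, i in zip((1, -1, 1, -1, 1), (3, 21, 44, 67, 90)):
            y[i] += sign * 5.0
        fit = fit_linear_regression(x, y)
        full = bonferroni_outlier_test(fit, n_max=100)
        assert len(full.indices) == 5
        rep = bonferroni_outlier_test(fit, n_max=3)
        assert len(rep.indices) == 3

    def test_adjusted_p_matches_reference_tool(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        y[4] += 6
        fit = fit_linear_regression(x, y)
        rep = bonferroni_outlier_test(fit, alpha=1.0, n_max=15)
        table = np.asarray(sm.OLS(y, sm.add_constant(x)).fit().outlier_test())
        for idx, adj in zip(rep.indices, rep.adjusted_p):
            assert adj == pytest.approx(min(float(table[idx, 2]), 1.0), rel=1e-9)

    def test_adjusted_at_least_raw(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(size=12)
        fit = bonferroni_outlier_test(
            fit_linear_regression(x, y), alpha=1.0, n_max=12
        )
        n = 12
        for idx, adj in zip(fit.indices, fit.adjusted_p):
            raw = adj / n if adj < 1 else adj
            assert adj >= raw


class TestHypergeometric:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_overlap(5, 5, 0, 20).p_value == pytest.approx(1.0)

    def test_full_overlap_exact_value(self):
        # P(X >= 5) = 1 / C(10,5) = 1/252
        res = hypergeometric_overlap(5, 5, 5, 10)
        assert res.p_value == pytest.approx(1 / 252)

    def test_matches_enumeration_for_small_universes(self):
        for universe in range(2, 16):
            for ka in range(1, universe + 1):
                for kb in range(1, universe + 1):
                    lo = max(0, ka + kb - universe)
                    for ov in range(lo, min(ka, kb) + 1):
                        got = hypergeometric_overlap(ka, kb, ov, universe).p_value
                        want = hypergeom_upper_tail(universe, ka, kb, ov)
                        assert got == pytest.approx(want, rel=1e-12)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(5, 5, 6, 20)
        with pytest.raises(ValueError):
            hypergeometric_overlap(25, 5, 2, 20)


class TestBhFdr:
    def test_single_value_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_applied_step_up(self):
        # 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 -> monotone cap at 0.04
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=100)
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_order_preserving(self, rng):
        p = rng.uniform(size=10)
        adj = bh_fdr(p)
        # adjusted values sorted by raw p are monotone non-decreasing
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


def aa_aln(rows):
    ids = [f"s{i}" for i in range(len(rows))]
    return MultipleAlignment(ids, rows, "amino_acid")


class TestBlosumPca:
    def test_identical_species_collapse_to_origin(self):
        res = blosum62_pca(aa_aln(["NHVQ"] * 4), [1, 2, 3, 4])
        assert np.allclose(res.coordinates, 0.0, atol=1e-8)
        assert np.allclose(res.score_matrix, res.score_matrix[0, 0])

    def test_two_clusters_separate_on_pc1(self):
        rows = ["NNNN", "NNNN", "HHHH", "HHHH"]
        res = blosum62_pca(aa_aln(rows), [1, 2, 3, 4])
        pc1 = res.coordinates[:, 0]
        assert pc1[0] == pytest.approx(pc1[1], abs=1e-8)
        assert pc1[2] == pytest.approx(pc1[3], abs=1e-8)
        assert abs(pc1[0] - pc1[2]) > 1.0

    def test_symmetry_and_eigenvalue_order(self, rng):
        alpha = list("ACDEFGHIKLMNPQRSTVWY-")
        rows = ["".join(rng.choice(alpha, size=12)) for _ in range(6)]
        res = blosum62_pca(aa_aln(rows), list(range(1, 13)))
        assert np.allclose(res.score_matrix, res.score_matrix.T)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_coordinates_reproduce_centered_similarities(self, rng):
        """Full-rank coordinates reconstruct the double-centered score matrix."""
        alpha = list("ACDEFGHIKLMNPQRSTVWY")
        rows = ["".join(rng.choice(alpha, size=10)) for _ in range(5)]
        res = blosum62_pca(aa_aln(rows), list(range(1, 11)))
        n = 5
        J = np.eye(n) - np.ones((n, n)) / n
        B = J @ res.score_matrix @ J
        # keep only the non-negative spectrum (classical MDS reconstruction)
        w, v = np.linalg.eigh(B)
        w_pos = np.clip(w, 0, None)
        B_pos = (v * w_pos) @ v.T
        assert np.allclose(res.coordinates @ res.coordinates.T, B_pos, atol=1e-6)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            blosum62_pca(aa_aln(["NH", "NH"]), [1, 2])
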