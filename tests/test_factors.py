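"""Latent-factor inference, residualization, per-gene factor r^2 and
covariate accounting."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import txdiv
from txdiv.exceptions import DegenerateDataError, InvalidParameterError


def _expr(values, unit="tmm_cpm"):
    values = np.asarray(values, dtype=float)
    return txdiv.ExpressionMatrix(
        values, unit,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )


def _factors(values):
    values = np.asarray(values, dtype=float)
    return txdiv.FactorSet(values, [f"s{j}" for j in range(values.shape[0])])


class TestFactorCountRule:
    @pytest.mark.parametrize("n,expected", [
        (120, 15), (150, 15), (151, 30), (250, 30),
        (251, 45), (300, 45), (350, 45), (351, 60), (851, 60),
    ])
    def test_printed_thresholds_and_boundaries(self, n, expected):
        assert txdiv.select_factor_count(n) == expected

    def test_rule_is_non_decreasing(self):
        counts = [txdiv.select_factor_count(n) for n in range(1, 900)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestInferFactors:
    def test_noise_free_single_axis_recovered_by_factor_one(self):
        rng = np.random.default_rng(0)
        axis = rng.standard_normal(40)
        loadings = rng.uniform(0.5, 2.0, size=60)
        expr = _expr(np.outer(loadings, axis) + 10)
        fset = txdiv.infer_factors(expr, 1)
        assert abs(spearmanr(fset.values[:, 0], axis).statistic) == pytest.approx(1.0)
        assert fset.provenance == "internal-PCA"

    def test_auto_uses_sample_size_rule(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.uniform(0, 5, size=(500, 400)))
        fset = txdiv.infer_factors(expr, "auto")
        assert fset.n_factors == 60

    def test_requesting_more_factors_than_rank_rejected(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.uniform(0, 5, size=(80, 50)))
        with pytest.raises(InvalidParameterError):
            txdiv.infer_factors(expr, 100)


class TestFactorCovariateCorrelations:
    def test_covariate_equal_to_one_factor_is_flagged(self):
        rng = np.random.default_rng(3)
        f = _factors(rng.standard_normal((60, 5)))
        table = txdiv.factor_covariate_correlations(f, f.values[:, 2])
        row = table.set_index("factor").loc["factor_3"]
        assert abs(row["spearman_rho"]) == pytest.approx(1.0)
        assert row["q_value"] < 1e-10
        assert row["significant"]

    def test_independent_covariate_about_five_percent_nominal(self):
        rng = np.random.default_rng(4)
        f = _factors(rng.standard_normal((100, 40)))
        hits = []
        for _ in range(50):
            table = txdiv.factor_covariate_correlations(f, rng.standard_normal(100))
            hits.append((table["p_value"] < 0.05).mean())
        assert 0.02 <= np.mean(hits) <= 0.08

    def test_constant_factor_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((30, 3))
        vals[:, 1] = 2.0
        with pytest.warns(UserWarning, match="factor_2"):
            table = txdiv.factor_covariate_correlations(_factors(vals), rng.standard_normal(30))
        assert np.isnan(table.loc[1, "spearman_rho"])
        assert not table.loc[1, "significant"]


class TestResidualize:
    def test_factor_proportional_to_covariate_vanishes(self):
        x = np.linspace(0, 1, 25)
        out = txdiv.residualize(_factors(2 * x[:, None]), x)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_orthogonal_centered_factor_unchanged(self):
        n = 40
        x = np.sin(np.arange(n))
        f = np.cos(2 * np.pi * np.arange(n) / n)
        f -= f.mean()
        xc = x - x.mean()
        f -= (f @ xc) / (xc @ xc) * xc  # exact orthogonality
        out = txdiv.residualize(_factors(f[:, None]), x)
        np.testing.assert_allclose(out.values[:, 0], f, atol=1e-12)

    def test_matches_closed_form_ols_and_kills_correlation(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(50)
        f = rng.standard_normal((50, 4))
        out = txdiv.residualize(_factors(f), x)
        xc = x - x.mean()
        for k in range(4):
            fc = f[:, k] - f[:, k].mean()
            beta = (fc @ xc) / (xc @ xc)
            np.testing.assert_allclose(out.values[:, k], fc - beta * xc, atol=1e-12)
            assert abs(np.corrcoef(out.values[:, k], x)[0, 1]) < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(30)
        f = _factors(rng.standard_normal((30, 3)))
        once = txdiv.residualize(f, x)
        twice = txdiv.residualize(once, x)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)


class TestGeneFactorR2:
    def test_gene_equal_to_a_factor_is_fully_explained(self):
        # the fit is on the rankit scale, so plant the factor as the
        # rankit image of the gene's expression
        rng = np.random.default_rng(8)
        z = rng.uniform(0, 5, 30)
        f = np.column_stack([txdiv.rankit(z), rng.standard_normal(30)])
        expr = _expr(np.vstack([z, rng.uniform(0, 5, 30)]))
        r2 = txdiv.gene_factor_r2(expr, _factors(f))
        assert r2[0] == pytest.approx(1.0, abs=1e-9)

    def test_null_gene_r2_mean_near_k_over_n_minus_one(self):
        rng = np.random.default_rng(9)
        n, k = 100, 10
        expr = _expr(rng.standard_normal((2000, n)) + 10)
        r2 = txdiv.gene_factor_r2(expr, _factors(rng.standard_normal((n, k))))
        assert np.nanmean(r2) == pytest.approx(k / (n - 1), abs=0.01)

    def test_saturated_fit_rejected(self):
        rng = np.random.default_rng(10)
        expr = _expr(rng.uniform(0, 5, size=(5, 10)))
        with pytest.raises(InvalidParameterError):
            txdiv.gene_factor_r2(expr, _factors(rng.standard_normal((10, 10))))


class TestAccount:
    def test_orthogonal_covariate_changes_nothing(self):
        rng = np.random.default_rng(11)
        n = 50
        f = rng.standard_normal((n, 4))
        expr = _expr(rng.uniform(0, 5, size=(100, n)))
        # construct a covariate orthogonal to every centered factor column
        v = rng.standard_normal(n)
        v -= v.mean()
        fc = f - f.mean(axis=0)
        q, _ = np.linalg.qr(fc)
        v -= q @ (q.T @ v)
        res = txdiv.account(expr, _factors(f), v)
        assert abs(res.delta_median) < 1e-6
        assert res.mw_p > 0.9

    def test_covariate_equal_to_factor_matches_drop_one_oracle(self):
        rng = np.random.default_rng(12)
        n, k = 60, 5
        f = rng.standard_normal((n, k))
        # orthogonalize so removing factor k equals residualizing on it
        q, _ = np.linalg.qr(f - f.mean(axis=0))
        f = q
        signal = (q @ rng.standard_normal((k, 100))).T * 2
        expr = _expr(np.abs(rng.standard_normal((100, n))) + signal + 10)
        res = txdiv.account(expr, _factors(f), f[:, 2])
        r_full = txdiv.gene_factor_r2(expr, _factors(f))
        r_drop = txdiv.gene_factor_r2(expr, _factors(np.delete(f, 2, axis=1)))
        oracle_delta = np.median(r_full) - np.median(r_drop)
        assert res.delta_median == pytest.approx(oracle_delta, abs=1e-9)

    def test_permuted_covariate_delta_centered_at_zero(self, std_tmm, std_factors,
                                                       std_diversity, std_pca):
        _, expr = std_tmm
        h_s = std_diversity["H_s"].to_numpy()
        rng = np.random.default_rng(13)
        deltas = [
            txdiv.account(expr, std_factors, rng.permutation(h_s), decomp=std_pca).delta_median
            for _ in range(25)
        ]
        assert abs(np.mean(deltas)) < 0.01

    def test_degenerate_covariate_rejected(self):
        rng = np.random.default_rng(14)
        expr = _expr(rng.uniform(0, 5, size=(20, 15)))
        with pytest.raises(DegenerateDataError):
            txdiv.account(expr, _factors(rng.standard_normal((15, 2))), np.ones(15))


def test_factor_variance_shares_sum_to_retained_pc_variance():
    """Factors taken as the top PCA scores of the matrix itself should
    jointly explain (almost exactly) the variance captured by those PCs."""
    rng = np.random.default_rng(15)
    expr = _expr(rng.uniform(0, 5, size=(300, 100)))
    decomp = txdiv.pca(expr)
    k = 5
    fset = txdiv.FactorSet(decomp.sample_scores[:, :k],
                           [f"s{j}" for j in range(100)])
    total = txdiv.factor_variance_total(expr, fset, decomp)
    assert total >= decomp.variance_fraction[:k].sum() - 1e-9
    assert total == pytest.approx(decomp.variance_fraction[:k].sum(), abs=0.05)
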