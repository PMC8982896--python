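"""Gene-wise association statistics, BH-FDR, rank tests and the
gene-attribute regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import txdiv
from txdiv.exceptions import DataFormatError, DegenerateDataError, InvalidParameterError


def _expr(values, unit="tmm_cpm"):
    values = np.asarray(values, dtype=float)
    return txdiv.ExpressionMatrix(
        values, unit,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )


def bh_oracle(p):
    """Literal BH step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        q[i] = min(running, 1.0)
    return q


class TestAssociate:
    def test_monotone_increasing_gene_has_unit_slope_on_the_rank_grid(self):
        n = 20
        x = np.linspace(0, 1, n) ** 3  # strictly increasing, no ties
        y = np.exp(np.linspace(2, 5, n))  # strictly increasing in x
        expr = _expr(y[None, :].repeat(3, axis=0) * np.array([[1.0], [2.0], [5.0]]))
        assoc = txdiv.associate(expr, x)
        np.testing.assert_allclose(assoc["gamma"], 1.0, atol=1e-12)
        assert (assoc["q_value"] < 1e-10).all()

    def test_monotone_decreasing_gene_mirrors_to_minus_one(self):
        n = 20
        x = np.arange(n, dtype=float)
        y = 10.0 - np.sqrt(1 + np.arange(n, dtype=float))
        assoc = txdiv.associate(_expr(y[None, :]), x)
        assert assoc.loc[0, "gamma"] == pytest.approx(-1.0, abs=1e-12)
        assert assoc.loc[0, "spearman_rho"] == pytest.approx(-1.0)

    def test_gamma_antisymmetric_under_covariate_negation(self):
        rng = np.random.default_rng(0)
        expr = _expr(rng.uniform(0, 10, size=(30, 25)))
        x = rng.standard_normal(25)
        a1 = txdiv.associate(expr, x)
        a2 = txdiv.associate(expr, -x)
        np.testing.assert_allclose(a1["gamma"], -a2["gamma"], atol=1e-10)
        np.testing.assert_allclose(a1["p_value"], a2["p_value"], atol=1e-10)

    def test_pvalues_invariant_under_monotone_covariate_transform(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.uniform(0, 10, size=(20, 30)))
        x = rng.uniform(1, 2, size=30)
        a1 = txdiv.associate(expr, x)
        a2 = txdiv.associate(expr, np.log(x) ** 3 + 5)
        np.testing.assert_allclose(a1["p_value"], a2["p_value"], atol=1e-12)

    def test_null_type_one_error_rate_close_to_nominal(self):
        rng = np.random.default_rng(11)
        expr = _expr(np.abs(rng.standard_normal((1000, 50))) + 1)
        assoc = txdiv.associate(expr, rng.standard_normal(50))
        frac = float((assoc["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_constant_gene_flagged_not_tested(self):
        vals = np.vstack([np.full(10, 3.0), np.arange(10.0)])
        assoc = txdiv.associate(_expr(vals), np.arange(10.0))
        assert not assoc.loc[0, "tested"]
        assert np.isnan(assoc.loc[0, "q_value"])
        assert assoc.loc[1, "tested"]

    def test_constant_covariate_degenerate(self):
        with pytest.raises(DegenerateDataError):
            txdiv.associate(_expr(np.arange(20.0).reshape(2, 10)), np.ones(10))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            txdiv.associate(_expr([[1.0, 2.0, 3.0]]), [1.0, 2.0, 3.0])


class TestBHAdjust:
    def test_hand_step_up_all_tied_at_the_top(self):
        np.testing.assert_allclose(
            txdiv.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_step_up_mixed(self):
        np.testing.assert_allclose(
            txdiv.bh_adjust([0.005, 0.04, 0.6]), [0.015, 0.06, 0.6]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(txdiv.bh_adjust([0.3]), [0.3])

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(InvalidParameterError):
                txdiv.bh_adjust(bad)

    @given(st.integers(1, 200), st.integers(0, 2**31 - 1))
    def test_matches_literal_step_up_oracle(self, m, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-12, 1.0, size=m)
        np.testing.assert_allclose(txdiv.bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestRankTests:
    def test_spearman_monotone_is_one(self):
        rho, _ = txdiv.spearman([1, 2, 3], [1, 4, 9])
        assert rho == pytest.approx(1.0)

    def test_mann_whitney_exact_enumeration_small_groups(self):
        u, p = txdiv.mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_mann_whitney_exact_matches_full_enumeration(self):
        x = [1.0, 4.0, 6.0, 9.0, 12.0]
        y = [2.0, 3.0, 7.0, 8.0, 10.0, 11.0, 13.0]
        u_obs, p = txdiv.mann_whitney(x, y)
        pooled = sorted(x + y)
        n1 = len(x)
        u_values = []
        for combo in itertools.combinations(range(len(pooled)), n1):
            ranks = np.asarray(combo) + 1
            u_values.append(ranks.sum() - n1 * (n1 + 1) / 2)
        u_values = np.asarray(u_values)
        mid = len(x) * len(y) / 2
        p_exact = np.mean(np.abs(u_values - mid) >= abs(u_obs - mid) - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_mann_whitney_exact_and_asymptotic_agree_at_n12(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            x = rng.standard_normal(5)
            y = rng.standard_normal(7) + 0.5
            _, p_exact = txdiv.mann_whitney(x, y)
            from scipy.stats import mannwhitneyu

            p_asym = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_kruskal_wallis_hand_rank_arithmetic(self):
        h, _ = txdiv.kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2)

    def test_kruskal_wallis_needs_two_groups(self):
        with pytest.raises(InvalidParameterError):
            txdiv.kruskal_wallis([1, 2, 3])


class TestSummarize:
    def test_no_significant_genes(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b"], "gamma": [1.0, -1.0], "q_value": [0.5, 0.5],
             "tested": [True, True]}
        )
        s = txdiv.summarize(table)
        assert s.n_significant == 0
        assert s.pct_significant == 0.0

    def test_counts_and_sign_split(self):
        table = pd.DataFrame(
            {"gene_id": list("abcd"), "gamma": [1.0, 2.0, 3.0, -1.0],
             "q_value": [0.01, 0.02, 0.03, 0.5], "tested": [True] * 4}
        )
        s = txdiv.summarize(table)
        assert (s.n_significant, s.pct_significant) == (3, 75.0)
        assert s.n_positive == 3 and s.pct_positive_of_significant == 100.0


class TestAttributeRegression:
    def _assoc_and_ann(self, rng, n_genes=400, length_beta=0.0):
        lengths = np.exp(rng.uniform(np.log(200), np.log(20000), n_genes))
        gc = rng.beta(18, 20, n_genes)
        mean_expr = np.exp(rng.normal(3, 1, n_genes))
        z_len = (np.log10(lengths) - np.log10(lengths).mean()) / np.log10(lengths).std(ddof=1)
        resp = length_beta * z_len + rng.standard_normal(n_genes) * 0.5
        assoc = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n_genes)],
             "gamma": resp, "p_value": np.full(n_genes, 0.5),
             "mean_expression": mean_expr, "tested": True}
        )
        # response is |gamma|; shift gamma positive so the planted slope survives
        assoc["gamma"] = resp - resp.min() + 0.1
        ann = txdiv.GeneAnnotation(
            pd.DataFrame(
                {"effective_length": np.round(lengths).astype(int), "gc_fraction": gc},
                index=pd.Index(assoc["gene_id"], name="gene_id"),
            )
        )
        return assoc, ann

    def test_planted_length_effect_recovered(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            assoc, ann = self._assoc_and_ann(rng, length_beta=2.0)
            res = txdiv.attribute_regression(assoc, ann)
            row = res.table.set_index("predictor").loc["effective_length"]
            se = abs(row["gamma"] / row["t_stat"])
            if abs(row["gamma"] - 2.0) < 3 * se:
                hits += 1
        assert hits >= 27  # >= 90% of replicates

    def test_null_response_slope_type_one_rate(self):
        sig = 0
        total = 0
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            assoc, ann = self._assoc_and_ann(rng, length_beta=0.0)
            res = txdiv.attribute_regression(assoc, ann)
            sig += int((res.table["p_value"] < 0.05).sum())
            total += 3
        assert 0.01 <= sig / total <= 0.10  # ~5% nominal

    def test_collinear_predictors_rejected_by_name(self):
        rng = np.random.default_rng(3)
        assoc, ann = self._assoc_and_ann(rng, n_genes=50)
        frame = ann.frame.copy()
        # GC an exact affine function of log-length -> rank-deficient design
        z = np.log10(frame["effective_length"].to_numpy(float))
        frame["gc_fraction"] = (z - z.min()) / (z.max() - z.min())
        with pytest.raises(DataFormatError, match="collinear"):
            txdiv.attribute_regression(assoc, txdiv.GeneAnnotation(frame))

    def test_constant_predictor_rejected_by_name(self):
        rng = np.random.default_rng(4)
        assoc, ann = self._assoc_and_ann(rng, n_genes=50)
        frame = ann.frame.copy()
        frame["gc_fraction"] = 0.5
        with pytest.raises(DataFormatError, match="gc_fraction"):
            txdiv.attribute_regression(assoc, txdiv.GeneAnnotation(frame))
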