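"""Gene-wise association of expression with a per-sample covariate.

Each gene's expression vector and the covariate are rank-inverse-normal
(rankit) transformed, then ordinary least squares y = b0 + gamma * x is fit
per gene; significance is the two-sided t-test on gamma with
Benjamini-Hochberg FDR across all tested genes. Spearman correlations are
reported on the untransformed values. A multiple regression of each gene's
association strength on gene length, GC content and mean expression
identifies which gene attributes predict the association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

from .exceptions import DataFormatError, DegenerateDataError, InvalidParameterError
from .io import GeneAnnotation
from .normalize import ExpressionMatrix, _rankit_matrix, rankit

__all__ = [
    "associate",
    "bh_adjust",
    "spearman",
    "mann_whitney",
    "kruskal_wallis",
    "summarize",
    "AssociationSummary",
    "attribute_regression",
    "AttributeRegressionResult",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise InvalidParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_covariate(covariate, n_samples: int) -> np.ndarray:
    x = np.asarray(covariate, dtype=float).ravel()
    if x.size != n_samples:
        raise DataFormatError(
            f"covariate has {x.size} values for {n_samples} samples"
        )
    if not np.isfinite(x).all():
        raise DataFormatError("covariate contains missing or non-finite values")
    if np.ptp(x) == 0:
        raise DegenerateDataError("covariate is constant")
    return x


def associate(expr: ExpressionMatrix, covariate,
              covariate_name: str = "covariate") -> pd.DataFrame:
    """Per-gene rankit-OLS association of expression with a covariate.

    Returns a DataFrame with one row per gene (input order): gamma, t_stat,
    p_value, q_value, spearman_rho, mean_expression, tested. Genes with
    constant expression are skipped (tested=False, NaN statistics) and
    excluded from the BH adjustment.
    """
    n = expr.n_samples
    if n < 4:
        raise InvalidParameterError("association requires at least 4 samples")
    x = _as_covariate(covariate, n)
    xr = rankit(x)
    y = expr.values
    tested = np.ptp(y, axis=1) > 0

    gamma = np.full(expr.n_genes, np.nan)
    t_stat = np.full(expr.n_genes, np.nan)
    p_value = np.full(expr.n_genes, np.nan)
    q_value = np.full(expr.n_genes, np.nan)
    rho = np.full(expr.n_genes, np.nan)

    if tested.any():
        yr = _rankit_matrix(y[tested])
        xc = xr - xr.mean()
        yc = yr - yr.mean(axis=1, keepdims=True)
        sxx = float(xc @ xc)
        g = (yc @ xc) / sxx
        ss_y = (yc**2).sum(axis=1)
        ss_res = np.clip(ss_y - g**2 * sxx, 0.0, None)
        df = n - 2
        se = np.sqrt(ss_res / df / sxx)
        with np.errstate(divide="ignore"):
            t = np.where(se > 0, g / np.where(se > 0, se, 1.0), np.sign(g) * np.inf)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        # a numerically perfect fit yields p = 0; clamp into BH's open domain
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        gamma[tested], t_stat[tested], p_value[tested] = g, t, p
        q_value[tested] = bh_adjust(p)
        # Spearman on untransformed values
        rx = stats.rankdata(x)
        ry = stats.rankdata(y[tested], axis=1)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean(axis=1, keepdims=True)
        denom = np.sqrt((ryc**2).sum(axis=1) * float(rxc @ rxc))
        rho[tested] = np.where(denom > 0, (ryc @ rxc) / np.where(denom > 0, denom, 1.0), np.nan)

    out = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "gamma": gamma,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "spearman_rho": rho,
            "mean_expression": y.mean(axis=1),
            "tested": tested,
        }
    )
    out.attrs["covariate"] = covariate_name
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; p from the
    t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise InvalidParameterError("spearman requires two equal-length vectors, length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("spearman undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample size is <= 12 and there are
    no cross-group ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InvalidParameterError("mann_whitney requires non-empty groups")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum test (chi-square approximation, tie-corrected)."""
    if len(groups) < 2:
        raise InvalidParameterError("kruskal_wallis requires at least 2 groups")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AssociationSummary:
    """Counts and percentages of significant gene-covariate associations."""

    n_genes: int
    n_tested: int
    n_significant: int
    n_positive: int
    n_negative: int
    alpha: float

    @property
    def pct_significant(self) -> float:
        return 100.0 * self.n_significant / self.n_tested if self.n_tested else 0.0

    @property
    def pct_positive_of_significant(self) -> float:
        return 100.0 * self.n_positive / self.n_significant if self.n_significant else 0.0

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_tested": self.n_tested,
            "n_significant": self.n_significant,
            "pct_significant": self.pct_significant,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "pct_positive_of_significant": self.pct_positive_of_significant,
            "alpha": self.alpha,
        }


def summarize(assoc: pd.DataFrame, alpha: float = 0.05) -> AssociationSummary:
    """Significant / non-significant counts and the sign split among
    significant genes (q < alpha, strictly)."""
    if len(assoc) == 0:
        raise InvalidParameterError("association table is empty")
    tested = assoc["tested"].to_numpy(bool)
    sig = tested & (assoc["q_value"].to_numpy(float) < alpha)
    pos = sig & (assoc["gamma"].to_numpy(float) > 0)
    neg = sig & (assoc["gamma"].to_numpy(float) < 0)
    return AssociationSummary(
        n_genes=len(assoc),
        n_tested=int(tested.sum()),
        n_significant=int(sig.sum()),
        n_positive=int(pos.sum()),
        n_negative=int(neg.sum()),
        alpha=alpha,
    )


@dataclass
class AttributeRegressionResult:
    """Joint OLS of per-gene association strength on gene attributes."""

    table: pd.DataFrame  # predictor, gamma, t_stat, p_value, q_value
    intercept: float
    n_genes: int
    response: str


_PREDICTORS = ("effective_length", "gc_fraction", "mean_expression")


def attribute_regression(assoc: pd.DataFrame, ann: GeneAnnotation,
                         response: str = "abs_gamma") -> AttributeRegressionResult:
    """Which gene attributes predict the strength of the diversity association?

    Regresses a per-gene association-strength response (``abs_gamma``
    default, ``neg_log10_p`` alternative) jointly on effective length, GC
    fraction and mean expression. Length and mean expression are
    log10-transformed and all three predictors standardized before the fit;
    BH adjustment is applied across the three slope p-values.
    """
    if response not in ("abs_gamma", "neg_log10_p"):
        raise InvalidParameterError(f"unknown response '{response}'")
    use = assoc[assoc["tested"]].copy()
    lengths = ann.lengths_for(use["gene_id"])
    gc = ann.gc_for(use["gene_id"])
    mean_expr = use["mean_expression"].to_numpy(float)
    ok = mean_expr > 0
    use, lengths, gc, mean_expr = use[ok], lengths[ok], gc[ok], mean_expr[ok]
    if len(use) < 5:
        raise InvalidParameterError("too few usable genes for attribute regression")

    raw = {
        "effective_length": np.log10(lengths),
        "gc_fraction": gc,
        "mean_expression": np.log10(mean_expr),
    }
    cols = []
    for name in _PREDICTORS:
        v = raw[name]
        sd = v.std(ddof=1)
        if sd == 0:
            raise DataFormatError(f"predictor '{name}' is constant: design is rank-deficient")
        cols.append((v - v.mean()) / sd)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name a column involved in the collinearity
        corr = np.corrcoef(design, rowvar=False)
        i, j = np.argwhere(np.triu(np.isclose(np.abs(corr), 1.0), k=1))[0]
        raise DataFormatError(
            f"predictors '{_PREDICTORS[i]}' and '{_PREDICTORS[j]}' are collinear: "
            "design is rank-deficient"
        )

    if response == "abs_gamma":
        y = np.abs(use["gamma"].to_numpy(float))
    else:
        y = -np.log10(use["p_value"].to_numpy(float))
    fit = OLS(y, add_constant(design)).fit()
    pvals = np.clip(fit.pvalues[1:], np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "predictor": list(_PREDICTORS),
            "gamma": fit.params[1:],
            "t_stat": fit.tvalues[1:],
            "p_value": pvals,
            "q_value": bh_adjust(pvals),
        }
    )
    return AttributeRegressionResult(table=table, intercept=float(fit.params[0]),
                                     n_genes=len(use), response=response)
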