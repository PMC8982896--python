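"""Latent expression factors and covariate accounting.

Broad unmeasured variation in an expression matrix is commonly summarized
by latent factors (PEER-style hidden covariates) and regressed out before
downstream analyses. The math here operates on factor vectors regardless
of how they were obtained: the default engine rankit-transforms every
retained gene and takes the top principal-component sample scores
(provenance "internal-PCA"); externally computed factors load from TSV
(provenance "external-file").

The accounting question — how much of the expression variance captured by
the factors is attributable to a covariate such as transcriptome
diversity — is answered by comparing per-gene coefficients of
determination r1^2 (expression ~ intact factors) against r2^2
(expression ~ factors with the covariate regressed out). The drop in the
median r^2 (delta_median) is the headline quantity; dividing it by the
total matrix variance explained by the factors gives accounted_fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decomposition import PCADecomposition, _pca_values, pca, query_variance
from .exceptions import DegenerateDataError, InvalidParameterError
from .io import FactorSet
from .association import bh_adjust, spearman, _as_covariate
from .normalize import ExpressionMatrix, _rankit_matrix

__all__ = [
    "select_factor_count",
    "infer_factors",
    "factor_covariate_correlations",
    "residualize",
    "gene_factor_r2",
    "account",
    "AccountingResult",
]

# sample-size dependent factor count: (upper sample bound, N)
FACTOR_COUNT_RULE = ((150, 15), (250, 30), (350, 45))
FACTOR_COUNT_MAX = 60


def select_factor_count(n_samples: int) -> int:
    """Recommended latent-factor count for a given sample size:
    15 up to 150 samples, 30 for 151-250, 45 for 251-350, 60 above 350."""
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be positive")
    for bound, n in FACTOR_COUNT_RULE:
        if n_samples <= bound:
            return n
    return FACTOR_COUNT_MAX


def infer_factors(expr: ExpressionMatrix, n_factors="auto") -> FactorSet:
    """Latent factors from rankit-PCA of a (gene-filtered) expression matrix.

    Every non-constant gene is rankit-transformed across samples, then the
    top ``n_factors`` PCA sample scores become the factors. ``"auto"``
    applies :func:`select_factor_count` (capped at the matrix rank).
    """
    keep = np.ptp(expr.values, axis=1) > 0
    if keep.sum() < 2:
        raise DegenerateDataError("fewer than 2 non-constant genes: cannot infer factors")
    max_allowed = min(expr.n_samples - 1, int(keep.sum()))
    if n_factors == "auto":
        n = min(select_factor_count(expr.n_samples), max_allowed)
    else:
        n = int(n_factors)
        if not (1 <= n <= max_allowed):
            raise InvalidParameterError(
                f"n_factors={n} exceeds the matrix rank bound "
                f"min(n_samples - 1, n_genes) = {max_allowed}"
            )
    yr = _rankit_matrix(expr.values[keep])
    decomp = _pca_values(yr.T, expr.sample_ids)
    n = min(n, decomp.n_pcs)
    return FactorSet(decomp.sample_scores[:, :n], expr.sample_ids.copy(),
                     np.array([f"factor_{k + 1}" for k in range(n)], dtype=object),
                     provenance="internal-PCA")


def factor_covariate_correlations(factors: FactorSet, covariate, alpha: float = 0.05):
    """Per-factor Spearman correlation with a covariate, BH across factors.

    Constant factor columns are skipped with a warning (NaN statistics).
    Returns a DataFrame: factor, spearman_rho, p_value, q_value, significant.
    """
    import pandas as pd

    x = _as_covariate(covariate, len(factors.sample_ids))
    rhos = np.full(factors.n_factors, np.nan)
    pvals = np.full(factors.n_factors, np.nan)
    usable = np.zeros(factors.n_factors, dtype=bool)
    for k in range(factors.n_factors):
        col = factors.values[:, k]
        if np.ptp(col) == 0:
            warnings.warn(
                f"factor '{factors.factor_ids[k]}' is constant; skipped", stacklevel=2
            )
            continue
        rho, p = spearman(x, col)
        rhos[k], pvals[k] = rho, min(max(p, np.finfo(float).tiny), 1.0)
        usable[k] = True
    qvals = np.full(factors.n_factors, np.nan)
    if usable.any():
        qvals[usable] = bh_adjust(pvals[usable])
    return pd.DataFrame(
        {
            "factor": factors.factor_ids,
            "spearman_rho": rhos,
            "p_value": pvals,
            "q_value": qvals,
            "significant": usable & (qvals < alpha),
        }
    )


def residualize(factors: FactorSet, covariate) -> FactorSet:
    """Regress a covariate out of every factor column (OLS with intercept);
    returns the residual factors, each uncorrelated with the covariate."""
    x = _as_covariate(covariate, len(factors.sample_ids))
    xc = x - x.mean()
    sxx = float(xc @ xc)
    f = factors.values
    fc = f - f.mean(axis=0, keepdims=True)
    beta = (xc @ fc) / sxx
    resid = fc - np.outer(xc, beta)
    return FactorSet(resid, factors.sample_ids.copy(), factors.factor_ids.copy(),
                     provenance=factors.provenance)


def gene_factor_r2(expr: ExpressionMatrix, factors: FactorSet) -> np.ndarray:
    """Per-gene coefficient of determination of rankit expression regressed
    jointly on all factors (with intercept). Constant genes get NaN."""
    factors = factors.aligned_to(expr.sample_ids)
    n, k = factors.values.shape
    if n <= k + 1:
        raise InvalidParameterError(
            f"saturated fit: {n} samples cannot support {k} factors plus intercept"
        )
    fc = factors.values - factors.values.mean(axis=0, keepdims=True)
    # orthonormal basis of the factor span, dropping numerically null
    # directions (e.g. a constant factor column)
    u, s, _ = np.linalg.svd(fc, full_matrices=False)
    tol = (s.max() * max(fc.shape) * np.finfo(float).eps) if s.size else 0.0
    q = u[:, s > tol]
    tested = np.ptp(expr.values, axis=1) > 0
    r2 = np.full(expr.n_genes, np.nan)
    if tested.any():
        yr = _rankit_matrix(expr.values[tested])
        yc = yr - yr.mean(axis=1, keepdims=True)
        proj = yc @ q
        ss_tot = (yc**2).sum(axis=1)
        ss_fit = (proj**2).sum(axis=1)
        r2[tested] = np.clip(ss_fit / ss_tot, 0.0, 1.0)
    return r2


@dataclass
class AccountingResult:
    """Variance explained by factors before/after removing a covariate."""

    covariate: str
    r1_sq: np.ndarray  # per-gene r^2, intact factors
    r2_sq: np.ndarray  # per-gene r^2, covariate-residualized factors
    median_r1_sq: float
    median_r2_sq: float
    delta_median: float
    v_total_factors: float
    accounted_fraction: float  # delta_median / v_total_factors (NaN if v_total 0)
    mw_p: float  # two-sided Mann-Whitney p between the two r^2 distributions

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "median_r1_sq": self.median_r1_sq,
            "median_r2_sq": self.median_r2_sq,
            "delta_median": self.delta_median,
            "v_total_factors": self.v_total_factors,
            "accounted_fraction": self.accounted_fraction,
            "mw_p": self.mw_p,
        }


def factor_variance_total(expr: ExpressionMatrix, factors: FactorSet,
                          decomp: PCADecomposition | None = None) -> float:
    """Total matrix variance attributable to the factor set: the sum over
    factor columns of the PCA query-variance of that column."""
    factors = factors.aligned_to(expr.sample_ids)
    if decomp is None:
        decomp = pca(expr)
    total = 0.0
    for k in range(factors.n_factors):
        col = factors.values[:, k]
        if np.ptp(col) == 0:
            continue
        total += query_variance(decomp, col, query_name=str(factors.factor_ids[k])).v_total
    return total


def account(expr: ExpressionMatrix, factors: FactorSet, covariate,
            covariate_name: str = "covariate",
            decomp: PCADecomposition | None = None) -> AccountingResult:
    """How much of the factor-explained expression variance does a covariate
    account for?

    Computes per-gene r^2 under intact factors (r1^2) and under factors with
    the covariate regressed out (r2^2); reports the medians, their
    difference, the difference normalized by the total variance the factors
    explain, and a two-sided Mann-Whitney p comparing the two per-gene r^2
    distributions. Pass a precomputed ``decomp`` (PCA of ``expr``) to reuse
    it across covariates.
    """
    factors = factors.aligned_to(expr.sample_ids)
    r1 = gene_factor_r2(expr, factors)
    r2 = gene_factor_r2(expr, residualize(factors, covariate))
    ok = ~np.isnan(r1) & ~np.isnan(r2)
    if not ok.any():
        raise DegenerateDataError("no usable genes for accounting")
    med1 = float(np.median(r1[ok]))
    med2 = float(np.median(r2[ok]))
    delta = med1 - med2
    v_total = factor_variance_total(expr, factors, decomp)
    accounted = delta / v_total if v_total > 0 else float("nan")
    if np.allclose(r1[ok], r2[ok]):
        mw_p = 1.0  # identical distributions; the rank test carries no signal
    else:
        mw_p = float(stats.mannwhitneyu(r1[ok], r2[ok], alternative="two-sided").pvalue)
    return AccountingResult(
        covariate=covariate_name,
        r1_sq=r1,
        r2_sq=r2,
        median_r1_sq=med1,
        median_r2_sq=med2,
        delta_median=delta,
        v_total_factors=v_total,
        accounted_fraction=accounted,
        mw_p=mw_p,
    )
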