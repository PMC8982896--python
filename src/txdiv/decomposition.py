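"""PCA of the expression matrix and the query-vector variance decomposition.

Samples are the observations and genes the variables; variables are
centered but not scaled (the common default of base-R ``prcomp``). The
per-sample coordinates on each principal component ("sample scores"; some
sources call these loadings) carry the variance fractions v_i.

The variance of the matrix attributable to a per-sample query vector (e.g.
transcriptome diversity) is

    v_total = sum_i r_i^2 * v_i

where r_i is the Pearson correlation between the rankit-transformed query
and the rankit-transformed scores of PC i. Because rankit is rank-based,
v_total is invariant under strictly monotone transforms of the query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, InvalidParameterError
from .normalize import ExpressionMatrix, rankit
from .association import bh_adjust, spearman

__all__ = [
    "PCADecomposition",
    "QueryVarianceResult",
    "PCCorrelationTable",
    "pca",
    "query_variance",
    "pc_correlation_table",
]

# components with eigenvalue below this are numerically null and dropped
_EIGENVALUE_FLOOR = 1e-12


@dataclass
class PCADecomposition:
    """Sample scores and variance fractions of an expression-matrix PCA."""

    sample_scores: np.ndarray  # (n_samples, n_pcs)
    variance_fraction: np.ndarray  # (n_pcs,)
    sample_ids: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.sample_scores.shape[1]


@dataclass
class QueryVarianceResult:
    """Per-PC r^2 against a query vector and the summed variance explained."""

    r_sq: np.ndarray
    v_total: float
    query_name: str


@dataclass
class PCCorrelationTable:
    """Per-PC Spearman correlations with a query, plus the best-PC record."""

    table: pd.DataFrame  # pc, spearman_rho, p_value, q_value, variance_fraction
    best_pc: int  # 1-based index of the PC with the largest |rho|
    best_rho: float
    best_variance_fraction: float


def _pca_values(x: np.ndarray, sample_ids: np.ndarray) -> PCADecomposition:
    """PCA of an observations-by-variables matrix (variables centered)."""
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total <= 0:
        raise DegenerateDataError("matrix has no variance: PCA undefined")
    keep = ev > _EIGENVALUE_FLOOR
    scores = u[:, keep] * s[keep]
    # deterministic sign: largest-magnitude coordinate of each score positive
    flip = np.sign(scores[np.argmax(np.abs(scores), axis=0), np.arange(scores.shape[1])])
    flip[flip == 0] = 1.0
    return PCADecomposition(scores * flip, ev[keep] / total, np.asarray(sample_ids, dtype=object))


def pca(expr: ExpressionMatrix) -> PCADecomposition:
    """Principal component analysis of an expression matrix."""
    if expr.n_samples < 2:
        raise InvalidParameterError("PCA requires at least 2 samples")
    if expr.n_genes < 2:
        raise InvalidParameterError("PCA requires at least 2 genes")
    return _pca_values(expr.values.T.astype(float), expr.sample_ids)


def _check_query(query, n_samples: int) -> np.ndarray:
    q = np.asarray(query, dtype=float).ravel()
    if q.size != n_samples:
        raise InvalidParameterError(
            f"query has {q.size} values for {n_samples} samples"
        )
    if not np.isfinite(q).all():
        raise InvalidParameterError("query contains missing or non-finite values")
    if np.ptp(q) == 0:
        raise DegenerateDataError("query vector is constant")
    return q


def query_variance(decomp: PCADecomposition, query, n_pcs: int | None = None,
                   query_name: str = "query") -> QueryVarianceResult:
    """Total matrix variance attributable to a per-sample query vector."""
    q = _check_query(query, decomp.sample_scores.shape[0])
    k = decomp.n_pcs if n_pcs is None else int(n_pcs)
    if not (1 <= k <= decomp.n_pcs):
        raise InvalidParameterError(f"n_pcs must lie in [1, {decomp.n_pcs}]")
    qr = rankit(q)
    qc = qr - qr.mean()
    r_sq = np.zeros(k)
    for i in range(k):
        scores = decomp.sample_scores[:, i]
        if np.ptp(scores) == 0:
            continue
        sr = rankit(scores)
        sc = sr - sr.mean()
        denom = np.sqrt((qc @ qc) * (sc @ sc))
        if denom > 0:
            r_sq[i] = float((qc @ sc) / denom) ** 2
    v_total = float((r_sq * decomp.variance_fraction[:k]).sum())
    return QueryVarianceResult(r_sq=r_sq, v_total=v_total, query_name=query_name)


def pc_correlation_table(decomp: PCADecomposition, query,
                         top_k: int = 8) -> PCCorrelationTable:
    """Spearman correlation of a query with each of the first ``top_k`` PC
    score vectors, BH-adjusted across those tests, plus the argmax-|rho| PC."""
    if top_k > decomp.n_pcs:
        raise InvalidParameterError(
            f"top_k={top_k} exceeds the number of components ({decomp.n_pcs})"
        )
    if top_k < 1:
        raise InvalidParameterError("top_k must be at least 1")
    q = _check_query(query, decomp.sample_scores.shape[0])
    rhos, pvals = [], []
    for i in range(top_k):
        rho, p = spearman(q, decomp.sample_scores[:, i])
        rhos.append(rho)
        pvals.append(min(max(p, np.finfo(float).tiny), 1.0))
    table = pd.DataFrame(
        {
            "pc": np.arange(1, top_k + 1),
            "spearman_rho": rhos,
            "p_value": pvals,
            "q_value": bh_adjust(np.asarray(pvals)),
            "variance_fraction": decomp.variance_fraction[:top_k],
        }
    )
    best = int(np.argmax(np.abs(np.asarray(rhos))))
    return PCCorrelationTable(
        table=table,
        best_pc=best + 1,
        best_rho=float(rhos[best]),
        best_variance_fraction=float(decomp.variance_fraction[best]),
    )
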