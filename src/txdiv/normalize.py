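"""Expression normalization: TPM, TMM scaling factors, the rank-based
inverse-normal (rankit) transform, and the low-expression gene filter.

TPM divides each gene's counts by its effective length and rescales every
sample to one million, removing length and depth effects within a sample.
TMM (trimmed mean of M-values) estimates a between-sample scaling factor
from trimmed log-ratios of gene proportions against a reference sample,
so that expression is comparable across libraries with different RNA
composition. The TMM algorithm is re-implemented here from its published
definition with the standard parameterization (log-ratio trim 0.30,
abundance trim 0.05, inverse-variance precision weights, reference chosen
by the 75th-percentile rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .exceptions import DataFormatError, DegenerateDataError, InvalidParameterError
from .io import CountMatrix, GeneAnnotation

__all__ = [
    "ExpressionMatrix",
    "NormalizationFactors",
    "compute_tpm",
    "compute_tmm",
    "rankit",
    "filter_genes",
]

# trim fractions and reference rule of the original TMM method
TMM_LOGRATIO_TRIM = 0.30
TMM_ABUNDANCE_TRIM = 0.05


@dataclass
class ExpressionMatrix:
    """Normalized expression values, genes x samples, tagged with their unit
    ("tpm" or "tmm_cpm")."""

    values: np.ndarray
    unit: str
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.unit not in ("tpm", "tmm_cpm"):
            raise InvalidParameterError(f"unknown expression unit '{self.unit}'")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError("expression matrix shape does not match id lists")
        if not np.isfinite(self.values).all():
            raise DataFormatError("expression values must be finite")
        if (self.values < 0).any():
            raise DataFormatError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(self.values[mask], self.unit,
                                self.gene_ids[mask], self.sample_ids.copy())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=list(self.sample_ids))


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1."""

    factors: np.ndarray
    sample_ids: np.ndarray
    reference_sample: str

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise DataFormatError("scaling factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-9:
            raise DataFormatError(f"scaling factors must have geometric mean 1 (got {gm!r})")


def compute_tpm(counts: CountMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Transcripts per million: length-normalized counts rescaled so every
    sample sums to 10^6. All-zero samples yield all-zero columns (warned)."""
    lengths = ann.lengths_for(counts.gene_ids)
    rate = counts.values / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(
            "all-zero sample(s) in TPM computation: "
            + ", ".join(map(str, counts.sample_ids[zero][:10])),
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, colsum)
    tpm = rate / safe * 1e6
    tpm[:, zero] = 0.0
    return ExpressionMatrix(tpm, "tpm", counts.gene_ids.copy(), counts.sample_ids.copy())


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """TMM factor of one sample against the reference (both raw counts)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2((obs / n_obs) / (ref / n_ref))
        abundance = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
        # asymptotic (delta-method) variance of the log-ratio
        weight_var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_ratio) & np.isfinite(abundance)
    log_ratio, abundance, weight_var = log_ratio[finite], abundance[finite], weight_var[finite]
    if log_ratio.size == 0 or np.max(np.abs(log_ratio)) < 1e-6:
        return 1.0
    n = log_ratio.size
    lo_l = np.floor(n * TMM_LOGRATIO_TRIM) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * TMM_ABUNDANCE_TRIM) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(log_ratio)
    rank_s = rankdata(abundance)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_ratio[keep] / weight_var[keep]) / np.sum(1.0 / weight_var[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def compute_tmm(counts: CountMatrix) -> tuple[NormalizationFactors, ExpressionMatrix]:
    """TMM scaling factors plus expression as counts-per-million scaled by
    the effective library size (library size x factor)."""
    if counts.n_samples < 2:
        raise InvalidParameterError("TMM requires at least 2 samples")
    x = counts.values.astype(float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = counts.sample_ids[lib == 0]
        raise DataFormatError(
            "sample(s) with zero total count: " + ", ".join(map(str, bad[:10]))
        )
    # reference: sample whose 75th-percentile proportion is closest to the mean
    p75 = np.quantile(x / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(p75 - p75.mean())))
    factors = np.array(
        [
            1.0 if s == ref_idx else _tmm_pair_factor(x[:, s], x[:, ref_idx], lib[s], lib[ref_idx])
            for s in range(counts.n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    expr = x / (lib * factors) * 1e6
    nf = NormalizationFactors(factors, counts.sample_ids.copy(),
                              str(counts.sample_ids[ref_idx]))
    return nf, ExpressionMatrix(expr, "tmm_cpm", counts.gene_ids.copy(),
                                counts.sample_ids.copy())


def rankit(v) -> np.ndarray:
    """Rank-based inverse-normal transform.

    Ties get average ranks; the transform maps rank r (of n) to the standard
    normal quantile at (r - 0.5) / n, so untied input lands on a fixed
    symmetric quantile grid with mean ~0.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InvalidParameterError("rankit requires a 1-d vector of length >= 2")
    if not np.isfinite(v).all():
        raise DataFormatError("rankit input must be finite")
    if np.ptp(v) == 0:
        raise DegenerateDataError("rankit input is constant")
    ranks = rankdata(v, method="average")
    return ndtri((ranks - 0.5) / v.size)


def _rankit_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise rankit without per-row validation (rows must be non-constant)."""
    n = values.shape[1]
    ranks = rankdata(values, method="average", axis=1)
    return ndtri((ranks - 0.5) / n)


def filter_genes(expr: ExpressionMatrix, min_value: float = 1.0,
                 min_fraction: float = 0.2) -> np.ndarray:
    """Low-expression gene mask: keep a gene iff it reaches ``min_value``
    in at least ``min_fraction`` of samples (both thresholds inclusive).

    Intended for TMM-scaled CPM, where the conventional cut is >= 1 CPM in
    >= 20% of samples before latent-factor inference.
    """
    if not (0 < min_fraction <= 1):
        raise InvalidParameterError("min_fraction must lie in (0, 1]")
    frac = (expr.values >= min_value).mean(axis=1)
    return frac >= min_fraction
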