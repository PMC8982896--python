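"""Transcriptome diversity: Shannon entropy of a sample's per-gene
transcript probabilities.

For a sample with counts c_i and effective lengths l_i the probability of
observing a transcript of gene i is

    p_i = (c_i / l_i) / sum_j (c_j / l_j)

and the sample's entropy is H = -sum_i p_i log2 p_i (bits), with
0 * log2 0 := 0. Normalizing by log2(G), where G is the number of expressed
genes in the sample, gives H_s in [0, 1]: 0 when all reads come from a
single gene, 1 when reads are spread evenly. Computing p_i from TPM values
instead of length-normalized counts gives identical probabilities, so both
inputs are accepted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, InvalidParameterError
from .io import CountMatrix, GeneAnnotation
from .normalize import ExpressionMatrix

__all__ = [
    "abundance",
    "shannon_entropy",
    "transcriptome_diversity",
    "downsample_diversity",
    "within_sample_variance",
]


def abundance(values, lengths=None) -> np.ndarray:
    """Per-gene transcript probability vector for one sample.

    ``values`` are raw counts (supply ``lengths``) or TPM (lengths already
    folded in). Zero-count genes get probability 0.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise InvalidParameterError("abundance input must be non-negative")
    if lengths is not None:
        lengths = np.asarray(lengths, dtype=float)
        if (lengths <= 0).any():
            raise InvalidParameterError("effective lengths must be positive")
        v = v / lengths
    total = v.sum()
    if total <= 0:
        raise DegenerateDataError("all-zero sample: abundance undefined")
    return v / total


def shannon_entropy(p) -> float:
    """Shannon entropy of a probability vector, in bits (0*log2(0) := 0)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() + 0.0)  # +0.0 avoids signed zero


def _diversity_column(p: np.ndarray, shared_g: int | None, sample_id) -> tuple[float, float, int]:
    g = int((p > 0).sum())
    h = shannon_entropy(p)
    denom_g = shared_g if shared_g is not None else g
    if denom_g <= 1:
        warnings.warn(
            f"sample '{sample_id}' has {g} expressed gene(s); H_s set to 0",
            stacklevel=3,
        )
        return h, 0.0, g
    return h, h / np.log2(denom_g), g


def transcriptome_diversity(matrix, ann: GeneAnnotation | None = None,
                            shared_genes: bool = False) -> pd.DataFrame:
    """Per-sample entropy H (bits) and normalized diversity H_s in [0, 1].

    Parameters
    ----------
    matrix
        A :class:`CountMatrix` (requires ``ann`` for effective lengths) or an
        :class:`ExpressionMatrix` with unit "tpm".
    shared_genes
        If True, normalize every sample by log2 of the total number of genes
        in the matrix instead of the per-sample expressed-gene count. The
        per-sample denominator is the default; the shared denominator makes
        H_s directly comparable across samples with different zero patterns.

    Returns a DataFrame with columns sample_id, H_bits, H_s, n_expressed,
    library_size, one row per sample in input order.
    """
    if isinstance(matrix, CountMatrix):
        if ann is None:
            raise InvalidParameterError(
                "count input requires a gene annotation with effective lengths"
            )
        lengths = ann.lengths_for(matrix.gene_ids)
        raw = matrix.values.astype(float)
        rate = raw / lengths[:, None]
    elif isinstance(matrix, ExpressionMatrix):
        if matrix.unit != "tpm":
            raise InvalidParameterError(
                f"expression input must be TPM, got unit '{matrix.unit}'"
            )
        raw = matrix.values
        rate = matrix.values
    else:
        raise InvalidParameterError("matrix must be a CountMatrix or ExpressionMatrix")

    shared_g = matrix.values.shape[0] if shared_genes else None
    records = []
    for j, sid in enumerate(matrix.sample_ids):
        col = rate[:, j]
        total = col.sum()
        if total <= 0:
            raise DegenerateDataError(f"all-zero sample '{sid}': diversity undefined")
        h, h_s, g = _diversity_column(col / total, shared_g, sid)
        records.append((sid, h, h_s, g, int(round(raw[:, j].sum()))))
    return pd.DataFrame.from_records(
        records, columns=["sample_id", "H_bits", "H_s", "n_expressed", "library_size"]
    )


def downsample_diversity(counts: CountMatrix, target_depth="auto", seed: int = 0,
                         ann: GeneAnnotation | None = None,
                         shared_genes: bool = False) -> pd.DataFrame:
    """Diversity after multinomially resampling every sample to a common depth.

    Equalizing sequencing depth this way is the control for depth-driven
    diversity differences: relative H_s values should be essentially
    unchanged. ``target_depth="auto"`` uses the smallest library size.
    If ``ann`` is omitted, genes are treated as having equal lengths.
    """
    lib = counts.library_sizes
    if target_depth == "auto":
        target = int(lib.min())
    else:
        target = int(target_depth)
    if target <= 0:
        raise InvalidParameterError("target depth must be a positive integer")
    too_small = lib < target
    if too_small.any():
        raise InvalidParameterError(
            f"target depth {target} exceeds library size of sample(s): "
            + ", ".join(map(str, counts.sample_ids[too_small][:10]))
        )
    rng = np.random.default_rng(seed)
    down = np.empty_like(counts.values)
    for j in range(counts.n_samples):
        col = counts.values[:, j]
        down[:, j] = rng.multinomial(target, col / col.sum())
    resampled = CountMatrix(down, counts.gene_ids.copy(), counts.sample_ids.copy())
    if ann is None:
        ones = pd.DataFrame(
            {"effective_length": np.ones(counts.n_genes, dtype=int),
             "gc_fraction": np.full(counts.n_genes, 0.5)},
            index=pd.Index(counts.gene_ids, name="gene_id"),
        )
        ann = GeneAnnotation(ones)
    return transcriptome_diversity(resampled, ann, shared_genes=shared_genes)


def within_sample_variance(expr: ExpressionMatrix) -> pd.Series:
    """Across-gene variance of expression per sample (n-1 denominator).

    A diagnostic: samples dominated by a few genes (low diversity) have high
    within-sample expression variance.
    """
    if expr.n_genes < 2:
        raise InvalidParameterError("within-sample variance requires >= 2 genes")
    var = expr.values.var(axis=0, ddof=1)
    return pd.Series(var, index=pd.Index(expr.sample_ids, name="sample_id"),
                     name="within_sample_variance")
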