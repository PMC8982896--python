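"""Readers, writers and validated in-memory containers for expression data.

Conventions
-----------
* Matrices are genes-in-rows, samples-in-columns, both on disk and in memory.
* Tabular files are tab-separated, UTF-8, header required, ``.`` decimal,
  no quoting. Count matrices may alternatively be MatrixMarket coordinate
  files accompanied by one-id-per-line sidecar files
  (``<base>.genes.txt`` / ``<base>.samples.txt``).
* Missing values are forbidden in count matrices; in sample-metadata
  numeric columns an empty field is read as NaN and propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as _spio
from scipy import sparse as _sparse

from .exceptions import DataFormatError

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "SampleTable",
    "FactorSet",
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "write_annotation",
    "read_samples",
    "write_samples",
    "read_factors",
    "write_factors",
]


def _check_unique(ids: np.ndarray, kind: str) -> None:
    if len(ids) != len(set(ids)):
        seen: set = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise DataFormatError(f"duplicate {kind} id(s): {', '.join(map(str, dups[:10]))}")


@dataclass
class CountMatrix:
    """Raw read counts per gene (rows) per sample (columns)."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise DataFormatError("count matrix must be two-dimensional")
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.isfinite(vals).all() or not (vals == np.floor(vals)).all():
                g, s = self._first_bad(~np.isfinite(vals) | (vals != np.floor(vals)))
                raise DataFormatError(
                    f"non-integer count at gene '{g}', sample '{s}'"
                )
            vals = vals.astype(np.int64)
        if (vals < 0).any():
            g, s = self._first_bad(vals < 0)
            raise DataFormatError(f"negative count at gene '{g}', sample '{s}'")
        self.values = vals

    def _first_bad(self, mask: np.ndarray) -> tuple:
        i, j = np.argwhere(mask)[0]
        return self.gene_ids[i], self.sample_ids[j]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total read count."""
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(frame.to_numpy(), frame.index.to_numpy(), frame.columns.to_numpy())


@dataclass
class GeneAnnotation:
    """Per-gene effective length (bp) and GC fraction.

    Wraps a DataFrame indexed by gene_id with columns ``effective_length``
    and ``gc_fraction``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("effective_length", "gc_fraction"):
            if col not in f.columns:
                raise DataFormatError(f"annotation missing required column '{col}'")
        _check_unique(f.index.to_numpy(), "gene")
        lengths = pd.to_numeric(f["effective_length"], errors="coerce")
        if lengths.isna().any() or (lengths < 1).any():
            bad = f.index[lengths.isna() | (lengths < 1)][0]
            raise DataFormatError(
                f"effective_length must be a positive integer; offending gene '{bad}'"
            )
        gc = pd.to_numeric(f["gc_fraction"], errors="coerce")
        if gc.isna().any() or (gc < 0).any() or (gc > 1).any():
            bad = f.index[gc.isna() | (gc < 0) | (gc > 1)][0]
            raise DataFormatError(f"gc_fraction must lie in [0, 1]; offending gene '{bad}'")
        f = f.copy()
        f["effective_length"] = lengths.astype(np.int64)
        f["gc_fraction"] = gc.astype(float)
        self.frame = f

    @property
    def gene_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def lengths_for(self, gene_ids) -> np.ndarray:
        """Effective lengths aligned to ``gene_ids``; missing genes are an error."""
        missing = [g for g in gene_ids if g not in self.frame.index]
        if missing:
            raise DataFormatError(
                "annotation missing effective length for gene(s): "
                + ", ".join(map(str, missing[:10]))
            )
        return self.frame.loc[list(gene_ids), "effective_length"].to_numpy(float)

    def gc_for(self, gene_ids) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.frame.index]
        if missing:
            raise DataFormatError(
                "annotation missing GC fraction for gene(s): " + ", ".join(map(str, missing[:10]))
            )
        return self.frame.loc[list(gene_ids), "gc_fraction"].to_numpy(float)


@dataclass
class SampleTable:
    """Per-sample metadata: arbitrary numeric or categorical covariates."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index.to_numpy(), "sample")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def check_samples(self, sample_ids) -> None:
        _check_sample_sets(self.sample_ids, sample_ids, "sample table")

    def column(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise DataFormatError(f"sample table has no column '{name}'")
        return self.frame[name]


@dataclass
class FactorSet:
    """Latent factors: one value per sample per factor.

    ``provenance`` records whether the factors were inferred internally
    ("internal-PCA") or loaded from an external file ("external-file").
    """

    values: np.ndarray
    sample_ids: np.ndarray
    factor_ids: np.ndarray = None
    provenance: str = "external-file"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataFormatError("factor matrix must be two-dimensional (samples x factors)")
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.factor_ids is None:
            self.factor_ids = np.array(
                [f"factor_{k + 1}" for k in range(self.values.shape[1])], dtype=object
            )
        self.factor_ids = np.asarray(self.factor_ids, dtype=object)
        if self.values.shape != (len(self.sample_ids), len(self.factor_ids)):
            raise DataFormatError(
                f"factor matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.factor_ids)} factors"
            )
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise DataFormatError("factor values must be finite")

    @property
    def n_factors(self) -> int:
        return self.values.shape[1]

    def check_samples(self, sample_ids) -> None:
        _check_sample_sets(self.sample_ids, sample_ids, "factor table")

    def aligned_to(self, sample_ids) -> "FactorSet":
        """Reorder rows to match ``sample_ids`` (sets must coincide)."""
        self.check_samples(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        order = [pos[s] for s in sample_ids]
        return FactorSet(self.values[order], np.asarray(sample_ids, dtype=object),
                         self.factor_ids.copy(), self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=list(self.factor_ids))


def _check_sample_sets(got, expected, what: str) -> None:
    got_s, exp_s = set(got), set(expected)
    if got_s != exp_s:
        extra = sorted(got_s - exp_s)
        missing = sorted(exp_s - got_s)
        parts = []
        if extra:
            parts.append(f"unexpected: {', '.join(map(str, extra[:10]))}")
        if missing:
            parts.append(f"missing: {', '.join(map(str, missing[:10]))}")
        raise DataFormatError(f"{what} sample ids do not match the matrix ({'; '.join(parts)})")


# ---------------------------------------------------------------------------
# readers / writers


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("") if path.suffix == ".mtx" else path
    return (base.with_name(base.name + ".genes.txt"),
            base.with_name(base.name + ".samples.txt"))


def read_count_matrix(path, fmt: str = "tsv") -> CountMatrix:
    """Read a gene-by-sample count matrix from TSV or MatrixMarket."""
    path = Path(path)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        vals = frame.apply(pd.to_numeric, errors="coerce").to_numpy(float)
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise DataFormatError(
                f"non-numeric count at gene '{frame.index[i]}', sample '{frame.columns[j]}' "
                f"in {path}"
            )
        return CountMatrix(vals, frame.index.to_numpy(), frame.columns.to_numpy())
    if fmt == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        for p in (genes_path, samples_path):
            if not p.exists():
                raise DataFormatError(f"MatrixMarket sidecar file not found: {p}")
        mat = _spio.mmread(path)
        if _sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = np.array(genes_path.read_text().split(), dtype=object)
        sample_ids = np.array(samples_path.read_text().split(), dtype=object)
        return CountMatrix(np.asarray(mat), gene_ids, sample_ids)
    raise DataFormatError(f"unknown count matrix format '{fmt}' (expected 'tsv' or 'mtx')")


def write_count_matrix(counts: CountMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        counts.to_frame().to_csv(path, sep="\t")
    elif fmt == "mtx":
        genes_path, samples_path = _mtx_sidecars(path)
        _spio.mmwrite(str(path), _sparse.coo_matrix(counts.values), field="integer")
        genes_path.write_text("\n".join(map(str, counts.gene_ids)) + "\n")
        samples_path.write_text("\n".join(map(str, counts.sample_ids)) + "\n")
    else:
        raise DataFormatError(f"unknown count matrix format '{fmt}' (expected 'tsv' or 'mtx')")


def read_annotation(path) -> GeneAnnotation:
    """Read a gene annotation TSV (gene_id, effective_length, gc_fraction)."""
    frame = pd.read_csv(Path(path), sep="\t")
    if "gene_id" not in frame.columns:
        raise DataFormatError(f"annotation file {path} missing required column 'gene_id'")
    return GeneAnnotation(frame.set_index("gene_id"))


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.frame.rename_axis("gene_id").reset_index().to_csv(path, sep="\t", index=False)


def read_samples(path) -> SampleTable:
    """Read a sample metadata TSV (sample_id + arbitrary covariate columns)."""
    frame = pd.read_csv(Path(path), sep="\t")
    if "sample_id" not in frame.columns:
        raise DataFormatError(f"sample table {path} missing required column 'sample_id'")
    return SampleTable(frame.set_index("sample_id"))


def write_samples(samples: SampleTable, path) -> None:
    samples.frame.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def read_factors(path, sample_ids=None) -> FactorSet:
    """Read a sample-by-factor TSV; optionally check against a sample set."""
    frame = pd.read_csv(Path(path), sep="\t")
    if "sample_id" not in frame.columns:
        raise DataFormatError(f"factor table {path} missing required column 'sample_id'")
    frame = frame.set_index("sample_id")
    vals = frame.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        col = vals.columns[vals.isna().any()][0]
        raise DataFormatError(f"factor table {path} has a non-numeric value in column '{col}'")
    fs = FactorSet(vals.to_numpy(float), frame.index.to_numpy(),
                   frame.columns.to_numpy(), provenance="external-file")
    if sample_ids is not None:
        fs.check_samples(sample_ids)
    return fs


def write_factors(factors: FactorSet, path) -> None:
    factors.to_frame().reset_index().to_csv(path, sep="\t", index=False)
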