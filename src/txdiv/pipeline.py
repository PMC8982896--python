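"""End-to-end orchestration: simulate/load -> normalize -> filter ->
diversity -> association -> variance decomposition -> factors -> accounting.

Every stage writes its tabular output under the configured directory, a
JSON manifest records the config hash, seed, per-stage status and file
checksums, and the machine-readable report aggregates the stage summaries.
The report itself is fully deterministic for a given config and seed;
wall-clock information lives only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate, summarize
from .decomposition import pca, pc_correlation_table, query_variance
from .diversity import downsample_diversity, transcriptome_diversity
from .exceptions import DataFormatError, InvalidParameterError, TxdivError
from .factors import account, factor_covariate_correlations, infer_factors
from .io import (
    read_annotation,
    read_count_matrix,
    read_factors,
    read_samples,
    write_factors,
)
from .normalize import compute_tmm, compute_tpm, filter_genes
from .simulate import SimulationConfig, generate_dataset, write_dataset

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

logger = logging.getLogger("txdiv")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    output_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    counts: str | None = None
    annotation: str | None = None
    metadata: str | None = None
    factors: str | None = None  # external factor TSV; None -> infer internally
    normalization: str = "tmm"
    alpha: float = 0.05
    filter_min_value: float = 1.0
    filter_min_fraction: float = 0.2
    n_factors: int | str = "auto"
    account_covariates: list[str] = field(default_factory=lambda: ["H_s"])
    downsample: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must lie in (0, 1)")
        if self.normalization not in ("tmm", "tpm"):
            raise InvalidParameterError("normalization must be 'tmm' or 'tpm'")
        if self.simulation is None and self.counts is None:
            raise InvalidParameterError("either a simulation config or a counts path is required")
        if "H_s" not in self.account_covariates:
            self.account_covariates = ["H_s", *self.account_covariates]

    def to_dict(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "counts": self.counts,
            "annotation": self.annotation,
            "metadata": self.metadata,
            "factors": self.factors,
            "normalization": self.normalization,
            "alpha": self.alpha,
            "filter_min_value": self.filter_min_value,
            "filter_min_fraction": self.filter_min_fraction,
            "n_factors": self.n_factors,
            "account_covariates": list(self.account_covariates),
            "downsample": self.downsample,
        }
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("tau_range", "length_range", "gc_beta_params"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


@dataclass
class PipelineReport:
    """Aggregated, deterministic results of one pipeline run."""

    diversity_summary: dict
    association_summary: dict
    v_total: dict  # query name -> total variance explained
    pc_table: list  # per-PC correlation records for H_s
    factor_correlations: list
    accounting: list  # one record per accounted covariate
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "diversity_summary": self.diversity_summary,
            "association_summary": self.association_summary,
            "v_total": self.v_total,
            "pc_table": self.pc_table,
            "factor_correlations": self.factor_correlations,
            "accounting": self.accounting,
            "provenance": self.provenance,
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _numeric_covariate(name: str, meta_frame: pd.DataFrame, div: pd.DataFrame) -> np.ndarray:
    """A per-sample numeric vector for a named covariate; categorical
    metadata columns are encoded as integer level codes."""
    if name == "H_s":
        return div["H_s"].to_numpy(float)
    col = meta_frame[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(float)
    return pd.Categorical(col).codes.astype(float)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis; see the module docstring for the stage order.

    Any stage failure aborts with the stage name; the manifest written to
    the output directory marks the run incomplete in that case.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "files": {},
        "complete": False,
    }
    stage = "setup"

    def _finish_stage(name: str, t0: float) -> None:
        manifest["stages"][name] = {"status": "ok", "seconds": round(time.monotonic() - t0, 3)}
        logger.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])

    def _write_manifest() -> None:
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")

    try:
        # ---- inputs -------------------------------------------------------
        stage = "inputs"
        t0 = time.monotonic()
        if config.simulation is not None:
            sim = SimulationConfig(**{**config.simulation.to_dict(), "seed": config.seed})
            write_dataset(sim, outdir / "simulated")
            counts, ann, meta, _ = generate_dataset(sim)
        else:
            counts = read_count_matrix(config.counts)
            ann = read_annotation(config.annotation) if config.annotation else None
            meta = read_samples(config.metadata) if config.metadata else None
        if meta is not None:
            meta.check_samples(counts.sample_ids)
            meta_frame = meta.frame.loc[list(counts.sample_ids)]
        else:
            meta_frame = pd.DataFrame(index=pd.Index(counts.sample_ids, name="sample_id"))
        missing = [c for c in config.account_covariates
                   if c != "H_s" and c not in meta_frame.columns]
        if missing:
            raise DataFormatError(
                "metadata is missing covariate column(s): " + ", ".join(missing)
            )
        _finish_stage(stage, t0)

        # ---- normalization ------------------------------------------------
        stage = "normalize"
        t0 = time.monotonic()
        if config.normalization == "tmm":
            nf, expr = compute_tmm(counts)
            pd.DataFrame({"sample_id": nf.sample_ids, "factor": nf.factors}).to_csv(
                outdir / "tmm_factors.tsv", sep="\t", index=False
            )
        else:
            if ann is None:
                raise DataFormatError("TPM normalization requires a gene annotation")
            expr = compute_tpm(counts, ann)
        expr.to_frame().to_csv(outdir / "expression.tsv", sep="\t")
        _finish_stage(stage, t0)

        # ---- gene filter (for factor inference) ---------------------------
        stage = "filter"
        t0 = time.monotonic()
        if expr.unit == "tmm_cpm":
            mask = filter_genes(expr, config.filter_min_value, config.filter_min_fraction)
        else:
            mask = np.ones(expr.n_genes, dtype=bool)
        filtered = expr.subset_genes(mask)
        pd.DataFrame({"gene_id": expr.gene_ids, "kept": mask}).to_csv(
            outdir / "gene_filter.tsv", sep="\t", index=False
        )
        _finish_stage(stage, t0)

        # ---- diversity ----------------------------------------------------
        stage = "diversity"
        t0 = time.monotonic()
        if ann is not None:
            div = transcriptome_diversity(counts, ann)
        else:
            div = transcriptome_diversity(compute_tpm_fallback(counts), None)
        div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        if config.downsample:
            div_ds = downsample_diversity(counts, "auto", seed=config.seed, ann=ann)
            div_ds.to_csv(outdir / "diversity_downsampled.tsv", sep="\t", index=False)
        h_s = div["H_s"].to_numpy(float)
        _finish_stage(stage, t0)

        # ---- association --------------------------------------------------
        stage = "associate"
        t0 = time.monotonic()
        assoc = associate(expr, h_s, covariate_name="H_s")
        assoc.to_csv(outdir / "association.tsv", sep="\t", index=False)
        assoc_summary = summarize(assoc, config.alpha).to_dict()
        _finish_stage(stage, t0)

        # ---- variance decomposition --------------------------------------
        stage = "variance"
        t0 = time.monotonic()
        decomp = pca(expr)
        v_total = {"H_s": query_variance(decomp, h_s, query_name="H_s").v_total}
        for name in config.account_covariates:
            if name == "H_s":
                continue
            vec = _numeric_covariate(name, meta_frame, div)
            if np.ptp(vec) > 0:
                v_total[name] = query_variance(decomp, vec, query_name=name).v_total
        pcs = pc_correlation_table(decomp, h_s, top_k=min(8, decomp.n_pcs))
        pcs.table.to_csv(outdir / "pc_correlations.tsv", sep="\t", index=False)
        _finish_stage(stage, t0)

        # ---- factors ------------------------------------------------------
        stage = "factors"
        t0 = time.monotonic()
        if config.factors is not None:
            fset = read_factors(config.factors, sample_ids=counts.sample_ids)
            fset = fset.aligned_to(counts.sample_ids)
        else:
            fset = infer_factors(filtered, config.n_factors)
        write_factors(fset, outdir / "factors.tsv")
        fcorr = factor_covariate_correlations(fset, h_s, alpha=config.alpha)
        fcorr.to_csv(outdir / "factor_correlations.tsv", sep="\t", index=False)
        _finish_stage(stage, t0)

        # ---- accounting ---------------------------------------------------
        stage = "account"
        t0 = time.monotonic()
        accounting = []
        for name in config.account_covariates:
            vec = _numeric_covariate(name, meta_frame, div)
            if np.ptp(vec) == 0:
                logger.warning("covariate '%s' is constant; skipped in accounting", name)
                continue
            res = account(expr, fset, vec, covariate_name=name, decomp=decomp)
            accounting.append(res.to_dict())
        pd.DataFrame(accounting).to_csv(outdir / "accounting.tsv", sep="\t", index=False)
        _finish_stage(stage, t0)

        report = PipelineReport(
            diversity_summary={
                "n_samples": int(len(div)),
                "H_s_mean": float(h_s.mean()),
                "H_s_sd": float(h_s.std(ddof=1)) if len(div) > 1 else 0.0,
                "H_s_min": float(h_s.min()),
                "H_s_max": float(h_s.max()),
            },
            association_summary=assoc_summary,
            v_total=v_total,
            pc_table=pcs.table.to_dict(orient="records"),
            factor_correlations=fcorr.to_dict(orient="records"),
            accounting=accounting,
            provenance={
                "txdiv_version": __version__,
                "seed": config.seed,
                "config_hash": manifest["config_hash"],
                "factor_provenance": fset.provenance,
                "n_factors": int(fset.n_factors),
                "n_genes_kept": int(mask.sum()),
            },
        )
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        for p in sorted(outdir.rglob("*.tsv")) + [outdir / "report.json"]:
            manifest["files"][str(p.relative_to(outdir))] = _file_checksum(p)
        manifest["complete"] = True
        _write_manifest()
        return report
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_manifest()
        if isinstance(exc, TxdivError):
            raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc
        raise


def compute_tpm_fallback(counts):
    """TPM with unit lengths, used when no annotation is supplied: length
    correction is then a no-op and diversity is computed from raw
    proportions."""
    import pandas as pd

    from .io import GeneAnnotation
    from .normalize import compute_tpm

    ones = GeneAnnotation(
        pd.DataFrame(
            {"effective_length": np.ones(counts.n_genes, dtype=int),
             "gc_fraction": np.full(counts.n_genes, 0.5)},
            index=pd.Index(counts.gene_ids, name="gene_id"),
        )
    )
    return compute_tpm(counts, ones)
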