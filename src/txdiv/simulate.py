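"""Synthetic RNA-seq count matrices with planted transcriptome-evenness
structure.

The generative model is compositional: each gene i has a positive baseline
molar abundance a_i (log-normal, normalized to sum 1). Per sample s an
evenness exponent tau_s reshapes the composition,

    m_is  propto  a_i ** tau_s ,

so tau < 1 flattens the profile (higher entropy) and tau > 1 sharpens it
(lower entropy): a sample's Shannon entropy is monotonically non-increasing
in tau for any non-uniform baseline. Reads are then drawn multinomially
with probability proportional to molar abundance x effective length x
2^(covariate log2 fold-changes), with the sample's library size drawn
jointly with tau through a Gaussian copula so sequencing depth can
correlate with evenness.

Every draw flows from one integer seed through a single generator, so a
configuration reproduces bit-identically. The recorded ground truth
includes the analytic expected sign of each gene's association with
diversity: lowering tau raises the relative abundance of genes whose log
baseline abundance sits below the abundance-weighted mean, so those genes
gain expression as diversity rises (sign +1) and genes above it lose
(sign -1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logsumexp, ndtr

from .exceptions import InvalidParameterError
from .io import (
    CountMatrix,
    GeneAnnotation,
    SampleTable,
    write_annotation,
    write_count_matrix,
    write_samples,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "evenness_profile",
           "generate_dataset", "write_dataset"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults describe a bulk RNA-seq cohort: 2000 genes x 200 samples at
    ~10^6 reads each, log-normal baseline abundances (sigma 1.5 on the
    natural-log scale), evenness exponents uniform on (0.75, 1.25), a mild
    negative tau-depth correlation (deeper libraries are more diverse),
    log-uniform gene lengths of 200-20000 bp, Beta(18, 20) GC fractions,
    and sex/batch multiplicative effects on 10% of genes.
    """

    n_genes: int = 2000
    n_samples: int = 200
    abundance_sigma: float = 1.5
    tau_range: tuple[float, float] = (0.75, 1.25)
    depth_log_mean: float = float(np.log(1e6))
    depth_log_sd: float = 0.2
    depth_tau_corr: float = -0.3
    length_range: tuple[int, int] = (200, 20000)
    gc_beta_params: tuple[float, float] = (18.0, 20.0)
    sex_effect_sd: float = 0.25
    batch_effect_sd: float = 0.15
    affected_fraction: float = 0.1
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise InvalidParameterError("n_genes must be at least 2")
        if self.n_samples < 1:
            raise InvalidParameterError("n_samples must be positive")
        if self.abundance_sigma <= 0:
            raise InvalidParameterError("abundance_sigma must be positive")
        lo, hi = self.tau_range
        if not (0 < lo <= hi):
            raise InvalidParameterError("tau_range bounds must be positive and ordered")
        if not (-1 <= self.depth_tau_corr <= 1):
            raise InvalidParameterError("depth_tau_corr must lie in [-1, 1]")
        llo, lhi = self.length_range
        if not (1 <= llo <= lhi):
            raise InvalidParameterError("length_range bounds must be >= 1 and ordered")
        a, b = self.gc_beta_params
        if a <= 0 or b <= 0:
            raise InvalidParameterError("gc_beta_params must be positive")
        if self.sex_effect_sd < 0 or self.batch_effect_sd < 0:
            raise InvalidParameterError("effect SDs must be non-negative")
        if not (0 <= self.affected_fraction <= 1):
            raise InvalidParameterError("affected_fraction must lie in [0, 1]")
        if self.n_batches < 1:
            raise InvalidParameterError("n_batches must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tau_range"] = list(self.tau_range)
        d["length_range"] = list(self.length_range)
        d["gc_beta_params"] = list(self.gc_beta_params)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("tau_range", "length_range", "gc_beta_params"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset."""

    tau: np.ndarray  # per-sample evenness exponent
    library_size: np.ndarray  # per-sample read total
    baseline_abundance: np.ndarray  # per-gene molar probability, sums to 1
    lengths: np.ndarray  # per-gene bp
    gc: np.ndarray  # per-gene GC fraction
    sex: np.ndarray  # per-sample label
    batch: np.ndarray  # per-sample label
    effect_log2fc: pd.DataFrame  # genes x covariate columns
    expected_assoc_sign: np.ndarray  # per-gene {-1, 0, +1}


def evenness_profile(a, tau: float) -> np.ndarray:
    """Reshape a molar composition by an evenness exponent: m_i propto a_i^tau.

    tau -> 0 flattens toward uniform, tau = 1 is the identity, tau > 1
    sharpens the profile; entropy is non-increasing in tau.
    """
    a = np.asarray(a, dtype=float)
    if tau <= 0:
        raise InvalidParameterError("tau must be positive")
    if (a <= 0).any():
        raise InvalidParameterError("baseline abundances must be strictly positive")
    log_m = tau * np.log(a)
    return np.exp(log_m - logsumexp(log_m))


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, GeneAnnotation, SampleTable, SyntheticTruth]:
    """Draw a full synthetic dataset: counts, annotation, metadata, truth."""
    rng = np.random.default_rng(config.seed)
    ng, ns = config.n_genes, config.n_samples

    gene_ids = np.array([f"g{i + 1:05d}" for i in range(ng)], dtype=object)
    sample_ids = np.array([f"s{j + 1:04d}" for j in range(ns)], dtype=object)

    log_a = rng.normal(0.0, config.abundance_sigma, size=ng)
    a = np.exp(log_a - logsumexp(log_a))

    llo, lhi = config.length_range
    lengths = np.rint(np.exp(rng.uniform(np.log(llo), np.log(lhi), size=ng))).astype(np.int64)
    lengths = np.clip(lengths, llo, lhi)
    gc = rng.beta(*config.gc_beta_params, size=ng)

    # joint (tau, log depth): Gaussian copula with the configured correlation
    rho = config.depth_tau_corr
    z1 = rng.standard_normal(ns)
    z2 = rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(ns)
    lo, hi = config.tau_range
    tau = lo + (hi - lo) * ndtr(z1)
    library_size = np.rint(np.exp(config.depth_log_mean + config.depth_log_sd * z2)).astype(np.int64)
    if (library_size < 1).any():
        raise InvalidParameterError("configured depth produced a zero library size")

    sex = rng.choice(np.array(["female", "male"], dtype=object), size=ns)
    batch = rng.choice(
        np.array([f"batch{b + 1}" for b in range(config.n_batches)], dtype=object), size=ns
    )

    n_affected = int(round(config.affected_fraction * ng))
    effects = {}
    # sex: females are the reference level
    fc_sex = np.zeros(ng)
    if n_affected and config.sex_effect_sd > 0:
        idx = rng.choice(ng, size=n_affected, replace=False)
        fc_sex[idx] = rng.normal(0.0, config.sex_effect_sd, size=n_affected)
    effects["sex_male"] = fc_sex
    # batches: batch1 is the reference level
    for b in range(1, config.n_batches):
        fc = np.zeros(ng)
        if n_affected and config.batch_effect_sd > 0:
            idx = rng.choice(ng, size=n_affected, replace=False)
            fc[idx] = rng.normal(0.0, config.batch_effect_sd, size=n_affected)
        effects[f"batch_batch{b + 1}"] = fc
    effect_log2fc = pd.DataFrame(effects, index=pd.Index(gene_ids, name="gene_id"))

    counts = np.empty((ng, ns), dtype=np.int64)
    for j in range(ns):
        m = evenness_profile(a, float(tau[j]))
        log2_effect = np.zeros(ng)
        if sex[j] == "male":
            log2_effect += effect_log2fc["sex_male"].to_numpy()
        if batch[j] != "batch1":
            log2_effect += effect_log2fc[f"batch_{batch[j]}"].to_numpy()
        w = np.log(m) + np.log(lengths) + log2_effect * np.log(2.0)
        p = np.exp(w - logsumexp(w))
        counts[:, j] = rng.multinomial(library_size[j], p)

    # genes below the abundance-weighted mean log-abundance gain relative
    # expression as diversity rises
    weighted_mean = float((a * np.log(a)).sum())
    expected_sign = np.sign(-(np.log(a) - weighted_mean)).astype(np.int64)

    ann = GeneAnnotation(
        pd.DataFrame(
            {"effective_length": lengths, "gc_fraction": gc},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    meta = SampleTable(
        pd.DataFrame(
            {"sex": sex, "batch": batch, "library_size": library_size},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SyntheticTruth(
        tau=tau,
        library_size=library_size,
        baseline_abundance=a,
        lengths=lengths,
        gc=gc,
        sex=sex,
        batch=batch,
        effect_log2fc=effect_log2fc,
        expected_assoc_sign=expected_sign,
    )
    return CountMatrix(counts, gene_ids, sample_ids), ann, meta, truth


def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Generate and write a dataset; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, ann, meta, truth = generate_dataset(config)
    paths = {
        "counts": outdir / "counts.tsv",
        "annotation": outdir / "annotation.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "config": outdir / "simulation.yaml",
    }
    write_count_matrix(counts, paths["counts"])
    write_annotation(ann, paths["annotation"])
    write_samples(meta, paths["metadata"])
    pd.DataFrame(
        {"sample_id": counts.sample_ids, "tau": truth.tau,
         "library_size": truth.library_size, "sex": truth.sex, "batch": truth.batch}
    ).to_csv(paths["truth_samples"], sep="\t", index=False)
    genes = pd.DataFrame(
        {"gene_id": counts.gene_ids, "baseline_abundance": truth.baseline_abundance,
         "effective_length": truth.lengths, "gc_fraction": truth.gc,
         "expected_assoc_sign": truth.expected_assoc_sign}
    )
    genes = genes.merge(truth.effect_log2fc.reset_index(), on="gene_id")
    genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return {k: str(v) for k, v in paths.items()}
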