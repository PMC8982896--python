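# txdiv — transcriptome diversity analysis for RNA-seq

RNA-seq expression estimates are compositional: every sample's counts are
relative, so any shift in how evenly reads are spread across genes moves
*every* gene's apparent expression. `txdiv` quantifies that evenness as
**transcriptome diversity** — the Shannon entropy of a sample's per-gene
transcript probabilities — and provides the downstream machinery to measure
how strongly it confounds expression analyses: per-gene association tests,
a PCA-based variance decomposition, and an accounting of how much of the
signal captured by PEER-style latent factors it explains. It is aimed at
people doing bulk or single-cell expression QC, eQTL covariate modelling,
or normalization methods work.

## The statistic

For a sample with read counts $c_i$ and effective gene lengths $l_i$, the
probability of observing a transcript of gene $i$ is

$$p_i = \frac{c_i / l_i}{\sum_j c_j / l_j},$$

identical to computing $p_i$ from TPM values. The sample's diversity is

$$H = -\sum_i p_i \log_2 p_i, \qquad
H_s = \frac{H}{\log_2 G} \in [0, 1],$$

with $G$ the number of expressed genes: $H_s = 0$ when one gene takes all
reads, $H_s = 1$ when reads are spread evenly. The companion analyses:

- **Association**: per gene, rankit-transformed expression is regressed on
  rankit-transformed $H_s$; two-sided *t*-tests on the slope $\gamma$ with
  Benjamini–Hochberg FDR.
- **Variance decomposition**: with PCA variance fractions $v_i$ and
  rankit-Pearson correlations $r_i$ between a query vector and PC scores,
  $v_\mathrm{total} = \sum_i r_i^2 v_i$ is the matrix variance the query
  explains.
- **Factor accounting**: per-gene $r_1^2$ (expression ~ intact latent
  factors) vs $r_2^2$ (factors with a covariate regressed out); the drop in
  the median, `delta_median`, measures how much of the factor signal that
  covariate accounts for.

A seeded synthetic-data generator plants known per-sample evenness
(exponent $\tau$: sample profiles $\propto a_i^{\tau}$), library sizes,
gene lengths/GC, and sex/batch effects, so every stage has a ground-truth
recovery test. TPM, TMM (re-implemented from the published trimmed
mean-of-M-values definition), the rankit transform and the ≥1 CPM in ≥20%
gene filter are built in.

## Worked example

```python
import txdiv
from scipy.stats import spearmanr

config = txdiv.SimulationConfig(n_genes=500, n_samples=60, seed=7)
counts, annotation, metadata, truth = txdiv.generate_dataset(config)
div = txdiv.transcriptome_diversity(counts, annotation)
print(div.head())
print("Spearman(H_s, planted tau) =",
      round(spearmanr(div.H_s, truth.tau).statistic, 3))
```

```
sample_id   H_bits      H_s  n_expressed  library_size
    s0001 8.203650 0.914995          500       1116733
    s0002 8.165474 0.910737          500       1071507
    s0003 7.578070 0.845767          498        786625
    s0004 7.716673 0.860680          500       1353146
    s0005 7.805536 0.870872          499        989236
Spearman(H_s, planted tau) = -1.0
```

Each row is one sample: entropy in bits, normalized diversity $H_s$, the
number of expressed genes and the library size. The perfect negative rank
correlation with the planted evenness exponent shows the statistic
recovers the simulated ground truth. The scripts in `examples/` continue
the story: `02_expression_association.py` finds 92.8% of genes associated
with diversity (58.6% of slopes positive) on a 1000-gene cohort,
`03_variance_explained.py` computes `v_total`, and
`04_factor_accounting.py` shows diversity dominating sex, batch and depth
in the factor accounting (`delta_median` 0.60 vs ≤ 0.08).

The same stages are scriptable from the shell:

```sh
txdiv simulate --out data/ --seed 7
txdiv diversity --input data/counts.tsv --annotation data/annotation.tsv --out div.tsv
txdiv run --config pipeline.yaml     # full pipeline + JSON report
```

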