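# Methods

## Transcriptome diversity

Per sample, gene-level transcript probabilities are
`p_i = (c_i / l_i) / Σ_j (c_j / l_j)` (counts over effective lengths), or
equivalently `p_i = TPM_i / Σ_j TPM_j`; the two routes agree to floating
point and both are implemented, with an equivalence test. Shannon entropy
`H = −Σ p_i log2 p_i` is computed in double precision with the
`0·log2 0 := 0` convention; no log-sum-exp stabilization is needed at
gene-level scales (p_i ≥ ~1e-12). The normalized statistic is
`H_s = H / log2(G)`.

**The denominator G.** `G` defaults to the number of genes with `p_i > 0`
in that sample, so the denominator varies across samples with different
zero patterns. A `shared_genes=True` switch normalizes every sample by the
total gene count of the matrix instead, which makes `H_s` strictly
comparable across samples; the per-sample convention is the default because
it treats each library's own support as the reference. For `G ≤ 1` the
denominator degenerates and `H_s` is defined as 0 (the zero-diversity
limit) with a warning.

**Depth equalization.** `downsample_diversity` resamples each sample
multinomially (reads with replacement) at a common target depth.
Hypergeometric (without-replacement) sampling would be marginally more
faithful but differs negligibly at the 10^5–10^6 depths where the control
is used.

## Normalization

- **TPM**: `(c_i/l_i) / Σ_j(c_j/l_j) × 10^6`; columns sum to 10^6 exactly;
  all-zero samples produce all-zero columns plus a warning rather than an
  error so that QC can proceed.
- **TMM** is re-implemented from the trimmed mean-of-M-values definition:
  reference sample by the 75th-percentile-closest-to-mean rule; per sample
  vs reference, genes zero in either are excluded; M = log2 ratio of
  proportions, A = mean log2 proportion; 30% two-sided trim on M and 5% on
  A (rank-based, average ties); the factor is the inverse-delta-method
  precision-weighted mean of the surviving M values; factors are rescaled
  to geometric mean 1, and a max |M| < 1e-6 short-circuit returns factor 1.
  TMM expression is reported as counts per effective-library-size million
  (`c / (library_size × factor) × 10^6`). The implementation reproduces the
  reference R implementation's factors on random matrices (checked during
  development) and a literal Python transcription of the definition in the
  test suite (tolerance 1e-8).
- **Rankit**: average-tied ranks mapped through `Φ⁻¹((rank − 0.5)/n)`. The
  (r − 0.5)/n offset is one of several conventions in circulation; it is
  symmetric, keeps extremes finite, and makes untied vectors land on a
  fixed quantile grid, which several exactness tests exploit. Constant
  vectors raise a degenerate-input error so callers decide whether to skip.
- **Gene filter**: keep a gene iff it reaches ≥ `min_value` (default 1
  TMM-CPM) in ≥ `min_fraction` (default 20%) of samples, both comparisons
  inclusive ("at least"). Applied before factor inference; association and
  PCA run on the unfiltered matrix in the pipeline.

## Association testing

Both the gene's expression vector and the covariate are rankit-transformed
before per-gene OLS, making slopes comparable across genes and p-values
invariant to monotone covariate transforms (property-tested). The t-test
on the slope uses n − 2 degrees of freedom; numerically perfect fits
(p = 0) are clamped to the smallest positive double before BH adjustment,
which operates on the open interval (0, 1]. Spearman correlations are
reported on untransformed values. Constant-expression genes are flagged
`tested = False` and excluded from the FDR family. BH is delegated to
statsmodels and verified against a literal step-up oracle.

Rank tests: Mann-Whitney uses exact enumeration when the pooled size is
≤ 12 and tie-free, otherwise the tie- and continuity-corrected normal
approximation; Kruskal-Wallis uses the tie-corrected chi-square
approximation; Spearman p-values use the t-approximation. All are scipy
wrappers with the tie policy fixed to average ranks.

**Attribute regression.** The per-gene response is |rankit-scale slope| by
default (a p-value-based response conflates sample size; `neg_log10_p` is
available behind a flag). Effective length and mean expression are log10
transformed — both are heavily right-skewed and would otherwise dominate
through a few extreme genes — and all three predictors (length, GC, mean
expression) are standardized, so coefficients are per-SD effects. Genes
with non-positive mean expression are dropped. BH is applied across the
regression's own three slope p-values. Rank-deficient designs are rejected
with the offending column named.

## Variance decomposition

PCA treats samples as observations and genes as variables; variables are
centered, not scaled (the common default of base-R `prcomp`). "Sample
scores" here are the per-sample PC coordinates (sometimes called loadings
in the expression literature — the naming is documented to avoid
convention confusion). Variance fractions use the total centered variance;
components with eigenvalue < 1e-12 are dropped. Score signs are fixed by
making each column's largest-magnitude entry positive, so results are
deterministic across runs and BLAS builds.

`query_variance` computes `v_total = Σ r_i² v_i` with Pearson r on
rankit-transformed query and scores, by default over all retained PCs.
Note that rank-transforming orthogonal score vectors leaves residual
sampling-level correlations of order 1/√n, so `v_total` for a query equal
to one PC's scores slightly exceeds that PC's `v_i` rather than matching
it exactly; tests assert closeness, not identity.

## Latent factors and accounting

The factor engine is pluggable because every computation operates on
factor vectors regardless of origin: the built-in engine rankit-transforms
each retained gene and takes the top PCA sample scores (provenance
`internal-PCA`); externally computed factor tables (e.g. PEER output) load
from TSV (provenance `external-file`). The variational-Bayes PEER model
itself is out of scope by design. The factor count follows the
sample-size rule (15 / 30 / 45 / 60 at ≤150 / 151–250 / 251–350 / >350
samples), capped at the matrix rank.

Per-gene factor regressions use rankit-transformed expression (consistent
with the association module) on all factors jointly with intercept;
r² is computed via an SVD-orthonormalized basis of the centered factor
span, which also silently drops numerically null directions such as a
constant factor column. Fits require `n_samples > n_factors + 1`.

`account` residualizes the covariate out of each factor column (OLS,
one covariate at a time — matching how multi-covariate comparisons are
usually presented — rather than jointly) and reports:

- `delta_median = median(r1²) − median(r2²)` — the headline quantity;
- `accounted_fraction = delta_median / v_total(factors)`, where
  `v_total(factors)` sums `query_variance` over factor columns — reported
  alongside because the raw-difference and normalized-ratio conventions
  both appear in practice and can differ by the factor-variance scale;
- a two-sided Mann-Whitney p between the two per-gene r² distributions
  (defined as 1 when the distributions are bitwise identical, where the
  rank test carries no information).

## Synthetic data

The generator emulates the statistical structure of real bulk RNA-seq
cohorts: log-normal baseline molar abundances (σ = 1.5 on the natural-log
scale, normalized to a composition), per-sample evenness exponents τ
(profiles ∝ a_i^τ, entropy non-increasing in τ) drawn uniform on
(0.75, 1.25), library sizes log-normal around 10^6 (σ_log = 0.2) coupled
to τ through a Gaussian copula (default correlation −0.3, i.e. deeper
libraries are more diverse), log-uniform gene lengths 200–20000 bp,
Beta(18, 20) GC fractions, and sex/batch log2 fold-changes (SD 0.25 /
0.15) on 10% of genes, applied multiplicatively to read probabilities
after τ and before renormalization (compositional closure is explicit).
Read probability is molar abundance × length, so the diversity module's
length correction is meaningful and testable. Counts are multinomial given
the library size; everything flows from one `numpy` generator seeded by a
single integer, so outputs are bit-identical across runs.

The defaults are also the scale of the heavier recovery tests (2000 genes
× 200 samples at ~10^6 reads), which keeps the full suite under a minute
for those stages while leaving multinomial sampling noise in H_s below
1e-3.

The recorded ground truth includes each gene's analytic expected
association sign: lowering τ raises the relative abundance of genes whose
log baseline abundance is below the abundance-weighted mean
`Σ_j a_j log a_j`, so those genes gain expression as diversity rises. This
derivation lives on the relative-abundance (TPM) scale; TMM's trimmed-mean
scaling re-anchors the composition at a different pivot, which flips genes
between the two pivots, so sign-recovery checks run against TPM
expression while magnitude/ranking checks use TMM. Under a log-normal
baseline the abundance-weighted mean exceeds the median log-abundance,
which is why most expected signs — and most observed significant
associations — are positive.

**What the generator does not model:** RNA-integrity decay, UMIs, isoform
structure, paired-end fragment-length effects, over-dispersed (negative
binomial) technical replicates, or correlated gene modules beyond the
single evenness axis. Passing recovery tests therefore demonstrate the
estimators are correct under the stated compositional model, not that real
datasets will show effects of the same size: in real data the diversity
axis competes with many other variance components, whereas here it is the
dominant planted driver.

## Pipeline

Stage order: inputs (simulate or load) → normalize → gene filter →
diversity (+ optional depth-equalized diversity) → association → PCA and
query variance → factors (inferred or external) → per-covariate
accounting. Categorical metadata covariates are encoded as integer level
codes for residualization — adequate for binary factors like sex; for
multi-level batches a one-hot treatment would be stricter and is a known
limitation. Every stage writes its TSV; `report.json` is fully
deterministic given config and seed (wall-clock timings live only in
`MANIFEST.json`, which also records the config hash and file checksums).
Any stage failure aborts with the stage name, leaving the manifest marked
incomplete.

## Known limitations

- TMM's reference-sample rule makes factors (and thus TMM-based results)
  dependent on the sample set; adding samples can change the reference.
- `v_total` is a rank-based second-moment summary; non-monotone
  relationships between a covariate and PC scores are under-counted.
- The internal PCA factor engine captures maximal-variance directions
  only; it stands in for PEER's posterior factors structurally, not
  numerically.
- The `G ≤ 1` convention (`H_s = 0`) is a limit choice; samples that
  degenerate this far should normally be excluded upstream.
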