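"""How much expression-matrix variance does transcriptome diversity explain?

PCA of the TMM matrix (samples as observations), then the query-vector
decomposition v_total = sum_i r_i^2 * v_i, where r_i is the rankit-Pearson
correlation between diversity and PC i's sample scores and v_i is that
PC's variance fraction.
"""

import txdiv

config = txdiv.SimulationConfig(n_genes=1000, n_samples=100, seed=13)
counts, annotation, metadata, truth = txdiv.generate_dataset(config)

_, expr = txdiv.compute_tmm(counts)
div = txdiv.transcriptome_diversity(counts, annotation)
h_s = div["H_s"].to_numpy()

decomp = txdiv.pca(expr)
result = txdiv.query_variance(decomp, h_s, query_name="H_s")
pcs = txdiv.pc_correlation_table(decomp, h_s, top_k=8)

print(pcs.table.to_string(index=False))
print(f"\nbest PC = PC{pcs.best_pc} (rho = {pcs.best_rho:.3f}, "
      f"variance fraction = {pcs.best_variance_fraction:.3f})")
print(f"v_total(H_s) = {result.v_total:.3f}")
print("v_total is the fraction of total expression variance attributable",
      "to diversity after summing its r^2 against every PC, weighted by",
      "each PC's variance share.")
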