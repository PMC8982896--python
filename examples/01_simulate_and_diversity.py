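"""Simulate an RNA-seq cohort with planted evenness and recover it.

Generates a 500-gene x 60-sample count matrix whose per-sample evenness
exponent tau is known, computes per-sample Shannon entropy H (bits) and
normalized transcriptome diversity H_s in [0, 1], and checks that H_s
tracks the planted tau (lower tau = more even profile = higher diversity).
"""

import numpy as np
from scipy.stats import spearmanr

import txdiv

config = txdiv.SimulationConfig(n_genes=500, n_samples=60, seed=7)
counts, annotation, metadata, truth = txdiv.generate_dataset(config)

div = txdiv.transcriptome_diversity(counts, annotation)
print(div.head().to_string(index=False))

rho = spearmanr(div["H_s"], truth.tau).statistic
print(f"\nSpearman(H_s, planted tau) = {rho:.3f}")
print("H_s ranges", f"{div['H_s'].min():.3f}-{div['H_s'].max():.3f};",
      "a strongly negative correlation means the entropy statistic",
      "recovers the planted per-sample evenness ranking.")
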