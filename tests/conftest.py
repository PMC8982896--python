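import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import txdiv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# one fixed seed for the reference synthetic cohort used across the suite
STD_SEED = 20


@pytest.fixture(scope="session")
def std_dataset():
    """Reference synthetic cohort at the default study scale
    (2000 genes x 200 samples, ~10^6 reads per sample)."""
    cfg = txdiv.SimulationConfig(seed=STD_SEED)
    return txdiv.generate_dataset(cfg)


@pytest.fixture(scope="session")
def std_tmm(std_dataset):
    counts, _, _, _ = std_dataset
    return txdiv.compute_tmm(counts)


@pytest.fixture(scope="session")
def std_tpm(std_dataset):
    counts, ann, _, _ = std_dataset
    return txdiv.compute_tpm(counts, ann)


@pytest.fixture(scope="session")
def std_diversity(std_dataset):
    counts, ann, _, _ = std_dataset
    return txdiv.transcriptome_diversity(counts, ann)


@pytest.fixture(scope="session")
def std_factors(std_tmm):
    _, expr = std_tmm
    mask = txdiv.filter_genes(expr)
    return txdiv.infer_factors(expr.subset_genes(mask))


@pytest.fixture(scope="session")
def std_pca(std_tmm):
    _, expr = std_tmm
    return txdiv.pca(expr)


@pytest.fixture
def small_counts():
    """Tiny hand-checkable count matrix."""
    return txdiv.CountMatrix(
        np.array([[10, 20], [10, 40], [5, 0]]),
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2"],
    )


@pytest.fixture
def small_annotation():
    return txdiv.GeneAnnotation(
        pd.DataFrame(
            {"effective_length": [1000, 2000, 500], "gc_fraction": [0.4, 0.5, 0.6]},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        )
    )
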