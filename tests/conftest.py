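import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from femtime.genemodels import GeneModel, Isoform
from femtime.simulate import SimulationConfig, simulate_all, simulate_expression


@pytest.fixture(scope="session")
def small_study():
    """A small noisy synthetic study shared across read-only tests."""
    return simulate_all(SimulationConfig(n_genes=120, seed=11))


@pytest.fixture(scope="session")
def noiseless_study():
    cfg = SimulationConfig(
        n_genes=60,
        seed=7,
        noise_sd=0.0,
        feature_noise_sd=0.0,
        zonation_noise_sd=0.0,
    )
    return simulate_all(cfg)


@pytest.fixture()
def two_exon_gene():
    return GeneModel(
        "g1", "chr1", "+", [Isoform("g1.1", [(100, 200), (300, 400)])]
    )


def expression_frame(gene_means, n_replicates=3, noise_sd=0.0, seed=0):
    """Small expression table from {gene: {condition: mean}}."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene, conds in gene_means.items():
        for cond, mean in conds.items():
            for rep in range(1, n_replicates + 1):
                noise = 2.0 ** rng.normal(0, noise_sd) if noise_sd else 1.0
                rows.append((gene, cond, rep, mean * noise))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "replicate", "fpkm"])
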