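import numpy as np
import pandas as pd
import pytest

from mrnastab import simulate
from mrnastab.containers import CountTable


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(n_genes=300, n_targets=50, seed=7, depth=5e5)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate.generate_truth(small_config)


@pytest.fixture(scope="session")
def small_counts(small_truth, small_config):
    return simulate.sample_counts(small_truth, small_config)


@pytest.fixture(scope="session")
def small_sequences(small_truth, small_config):
    return simulate.generate_sequences(small_truth, small_config)


@pytest.fixture()
def toy_counts():
    """2 genotypes x 2 assays x 2 replicates, 4 genes, hand-set counts."""
    rng = np.random.default_rng(11)
    rows = []
    for genotype in ("WT", "KO"):
        for assay in ("nascent_4sU", "total"):
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{assay}_r{rep}",
                        "assay": assay,
                        "genotype": genotype,
                        "replicate": rep,
                    }
                )
    sheet = pd.DataFrame(rows)
    counts = pd.DataFrame(
        rng.integers(10, 1000, size=(4, len(sheet))).astype(float),
        index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"),
        columns=sheet["sample_id"].tolist(),
    )
    return CountTable(counts=counts, samples=sheet)
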