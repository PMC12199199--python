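import numpy as np
import pandas as pd
import pytest

from evref import CqTable, ExpressionMatrix, GeneAnnotation, ReplicateMap


@pytest.fixture
def toy_counts():
    """3 genes × 2 samples raw counts with annotated lengths."""
    counts = ExpressionMatrix(
        pd.DataFrame({"s1": [10.0, 90.0, 400.0], "s2": [5.0, 45.0, 200.0]},
                     index=["g1", "g2", "g3"]),
        unit="counts")
    annotation = GeneAnnotation(pd.DataFrame(
        {"symbol": ["A", "B", "C"],
         "biotype": ["protein_coding", "lncRNA", "protein_coding"],
         "length_bp": [1000.0, 2000.0, 500.0]},
        index=["g1", "g2", "g3"]))
    return counts, annotation


@pytest.fixture
def two_source_matrix():
    """4 genes × 5 samples (source A triplicate, source B duplicate)."""
    values = pd.DataFrame(
        {"A_r1": [5.0, 4.0, 8.0, 1.0],
         "A_r2": [0.0, 6.0, 9.0, 1.0],
         "A_r3": [7.0, 5.0, 7.0, 1.0],
         "B_r1": [3.0, 0.0, 2.0, 1.0],
         "B_r2": [4.0, 5.0, 3.0, 1.0]},
        index=["g1", "g2", "g3", "g4"])
    matrix = ExpressionMatrix(values, unit="rpkm")
    replicates = ReplicateMap({"A_r1": "A", "A_r2": "A", "A_r3": "A",
                               "B_r1": "B", "B_r2": "B"})
    return matrix, replicates


def random_cq_table(rng: np.random.Generator, n_genes: int = 5,
                    n_samples: int = 12) -> CqTable:
    """Random but realistic Cq table: gene level + sample shift + noise."""
    gene_level = rng.uniform(18, 32, size=(n_genes, 1))
    sample_shift = rng.normal(0, 1.0, size=(1, n_samples))
    noise = rng.normal(0, 0.8, size=(n_genes, n_samples))
    cq = gene_level + sample_shift + noise
    return CqTable(pd.DataFrame(
        cq, index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)]))


@pytest.fixture
def cq_4x5():
    rng = np.random.default_rng(42)
    return random_cq_table(rng, n_genes=4, n_samples=5)
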