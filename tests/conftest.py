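import numpy as np
import pandas as pd
import pytest

from mycsig import DirectionalSignature, ExpressionMatrix, GeneSet


@pytest.fixture
def four_gene_signature():
    return DirectionalSignature(
        name="toy", entries={"A": 1, "B": 1, "C": -1, "D": -1}
    )


@pytest.fixture
def centered_matrix():
    """4 genes x 3 samples on the log2-centered scale."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 1.0, -1.0, -1.0],
            "s2": [-1.0, -1.0, 1.0, 1.0],
            "s3": [2.0, 0.0, -1.0, 1.0],
        },
        index=["A", "B", "C", "D"],
    )
    return ExpressionMatrix(data, scale="log2-centered")


@pytest.fixture
def immune_set():
    return GeneSet(name="imm", description="toy immune set", genes=["A", "B"])


def random_centered_matrix(rng, n_genes, n_samples):
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    data = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)), index=genes, columns=samples
    )
    return ExpressionMatrix(data, scale="log2-centered")
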