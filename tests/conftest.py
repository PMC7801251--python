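import numpy as np
import pytest

from dctnet import ExpressionMatrix, SyntheticSpec, generate_paired_dataset


@pytest.fixture
def tiny_table(tmp_path):
    """3-gene x 2-tissue TSV: g1:(1,2), g2:(0,0), g3:(5,1)."""
    path = tmp_path / "tiny.tsv"
    path.write_text(
        "gene_id\troot\tleaf\n"
        "g1\t1\t2\n"
        "g2\t0\t0\n"
        "g3\t5\t1\n"
    )
    return path


@pytest.fixture
def small_pair():
    """Random nonnegative paired matrices (3 tissues x 50 genes), seed 0."""
    rng = np.random.default_rng(0)
    tissues = ["t1", "t2", "t3"]
    genes = [f"g{i}" for i in range(50)]
    X1 = ExpressionMatrix("case", tissues, genes, rng.uniform(0, 10, (3, 50)))
    X2 = ExpressionMatrix("control", tissues, genes,
                          rng.uniform(0, 10, (3, 50)))
    return X1, X2


@pytest.fixture(scope="session")
def default_synthetic():
    """Default-parameter synthetic dataset, seed 1 (shared across tests)."""
    return generate_paired_dataset(SyntheticSpec(seed=1))


def random_h(rng, k=7, n=10, scale=5.0):
    return rng.uniform(0.1, scale, size=(k, n))
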