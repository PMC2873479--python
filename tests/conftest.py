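import numpy as np
import pytest

from generank import ExpressionMatrix


@pytest.fixture
def micro_matrix():
    """One gene, values [2, 4 | 0, 2], labels [+, +, -, -].

    Class means 3 and 1; population SDs 1 and 1; sample variances 2 and 2.
    """
    return ExpressionMatrix(
        values=np.array([[2.0, 4.0, 0.0, 2.0]]),
        gene_ids=["g1"],
        sample_ids=["s1", "s2", "s3", "s4"],
        labels=[1, 1, -1, -1],
    )


@pytest.fixture
def toy_1d_svm():
    """Two 1-D samples at -1 and +1 with matching labels."""
    return ExpressionMatrix(
        values=np.array([[-1.0, 1.0]]),
        gene_ids=["g1"],
        sample_ids=["a", "b"],
        labels=[-1, 1],
    )


def random_matrix(rng, n_genes=20, n_pos=6, n_neg=6, integer_values=False):
    """Unstructured two-class matrix; integer values inject expression ties."""
    s = n_pos + n_neg
    if integer_values:
        values = rng.integers(0, 6, size=(n_genes, s)).astype(float)
    else:
        values = rng.normal(size=(n_genes, s))
    labels = np.array([1] * n_pos + [-1] * n_neg)
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(s)],
        labels=labels,
    )
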