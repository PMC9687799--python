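import numpy as np
import pandas as pd
import pytest

from tcburden import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, log2 scale, hand-checkable."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [2.0, 2.0, 2.0, 5.0]],
        index=["GA", "GB", "GC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(values=values, scale="log2")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_log2_matrix(rng, n_genes=8, n_samples=6) -> ExpressionMatrix:
    values = pd.DataFrame(
        rng.normal(8, 2, size=(n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(values=values, scale="log2")
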