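import numpy as np
import pytest

from cgflow import normalize, simulate
from cgflow.containers import CountMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """Deterministic 6 cells × 4 genes counts with no zero margins."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [3, 1, 0, 2],
            [0, 2, 4, 1],
            [2, 3, 1, 0],
            [4, 1, 1, 3],
            [1, 2, 3, 2],
        ]
    )
    return CountMatrix(counts, [f"c{i}" for i in range(6)], [f"g{j}" for j in range(4)])


@pytest.fixture
def block_expression():
    """Standardized residuals of a 2-block synthetic dataset (fast size)."""
    spec = simulate.SyntheticSpec(
        n_cells=500, n_genes=80, block_sizes=(20, 20), rho_within=0.8, seed=7
    )
    counts, labels = simulate.generate_block_counts(spec)
    expr = normalize.standardize(normalize.pearson_residuals(counts))
    return expr, labels


@pytest.fixture
def gaussian_expression(rng):
    """Standardized iid Gaussian 'expression' (no count structure)."""
    x = rng.standard_normal((30, 400))
    x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
    return ExpressionMatrix(
        x, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(400)], standardized=True
    )
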