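import numpy as np
import pytest

from ssber.io_preprocess import ExpressionMatrix


def make_matrix(values, batch="b1", layer="counts", prefix="c"):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionMatrix(
        values,
        np.array([f"{batch}|{prefix}{i}" for i in range(n)], dtype=object),
        np.array([f"g{j}" for j in range(g)], dtype=object),
        np.repeat(batch, n).astype(object),
        layer,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def counts_matrix(rng):
    """A modest random counts matrix (30 cells × 20 genes, one batch)."""
    return make_matrix(rng.poisson(3.0, size=(30, 20)) + 0.0)
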