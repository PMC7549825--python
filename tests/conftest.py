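import numpy as np
import pytest

from setbridge import ExpressionMatrix, GeneSet, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_collection():
    return GeneSetCollection(
        "toy",
        [
            GeneSet("S1", ("g0", "g1", "g2", "g3", "g4")),
            GeneSet("S2", ("g3", "g4", "g5", "g6")),
            GeneSet("S3", ("g10", "g11", "g12", "g13", "g14", "g15")),
        ],
    )


@pytest.fixture
def small_expression(rng):
    n_genes, n_samples = 30, 6
    values = rng.normal(8.0, 2.0, size=(n_genes, n_samples))
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
        platform="array",
    )
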