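import numpy as np
import pytest

from minegs import (
    BindingMatrix,
    ExpressionDataset,
    GeneNetwork,
    GeneSetCollection,
)


def random_connected_weighted_graph(m: int, rng: np.random.Generator, p: float = 0.4) -> np.ndarray:
    """Symmetric positively weighted connected graph on m nodes (chain backbone)."""
    W = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if rng.random() < p:
                w = rng.uniform(0.1, 1.0)
                W[i, j] = W[j, i] = w
    for i in range(m - 1):
        if W[i, i + 1] == 0:
            w = rng.uniform(0.1, 1.0)
            W[i, i + 1] = W[i + 1, i] = w
    return W


@pytest.fixture
def toy_expression() -> ExpressionDataset:
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [1.0, 2.0, 3.0, 5.0],
            [4.0, 3.0, 2.0, 1.0],
        ]
    )
    return ExpressionDataset(("a", "b", "c"), ("s1", "s2", "s3", "s4"), values, ("A", "A", "B", "B"))


@pytest.fixture
def toy_binding() -> BindingMatrix:
    Z = np.array([[1, 1, 0], [0, 1, 1], [0, 0, 0]])
    return BindingMatrix(("a", "b", "c"), ("m1", "m2", "m3"), Z)


@pytest.fixture
def toy_network() -> GeneNetwork:
    return GeneNetwork(("a", "b", "c"), frozenset({("a", "b"), ("b", "c")}))


@pytest.fixture
def toy_gene_sets() -> GeneSetCollection:
    coll = GeneSetCollection()
    coll.add("set1", ["a", "b", "c"], source="toy")
    coll.add("set2", ["c", "d"], source="toy")
    return coll
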