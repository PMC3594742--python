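import itertools

import numpy as np
import pytest

from mica.datatypes import EdgeList, ExpressionMatrix


def make_expr(values, gene_prefix="g", sample_prefix="s") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i + 1}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def two_triangles() -> EdgeList:
    tri = lambda names: {frozenset(p) for p in itertools.combinations(names, 2)}
    nodes = ["a1", "a2", "a3", "b1", "b2", "b3"]
    return EdgeList(nodes, tri(nodes[:3]) | tri(nodes[3:]))


@pytest.fixture
def two_cliques_k5() -> EdgeList:
    """Two disjoint 5-cliques: enough links for crisp separation at the
    default priors."""
    clique = lambda names: {frozenset(p) for p in itertools.combinations(names, 2)}
    a = [f"a{i}" for i in range(5)]
    b = [f"b{i}" for i in range(5)]
    return EdgeList(a + b, clique(a) | clique(b))


def gxe_pair(n=100, noise=0.1, seed=0, shift=6.0):
    """A shifted/flipping gene pair: piecewise-linear relationship with
    opposite slopes per condition (pooled r ~ 0, MIC ~ 1)."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    f = (f - f.mean()) / f.std()
    c = np.zeros(n)
    c[rng.choice(n, n // 2, replace=False)] = 1
    x = f + shift * c + rng.normal(0, noise, n)
    y = f * (1 - 2 * c) + rng.normal(0, noise, n)
    return x, y, c
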