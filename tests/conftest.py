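import numpy as np
import pytest

from comodule import CoexpressionNetwork, ExpressionMatrix


def net_from_edges(genes, edges):
    """Build a CoexpressionNetwork from a list of gene-ID pairs."""
    idx = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((len(genes), len(genes)), dtype=np.int8)
    for a, b in edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
    return CoexpressionNetwork(list(genes), adj)


def random_net(n, p, rng, prefix="g"):
    """Erdos-Renyi network on n genes with edge probability p."""
    genes = [f"{prefix}{i}" for i in range(n)]
    adj = np.zeros((n, n), dtype=np.int8)
    iu = np.triu_indices(n, k=1)
    adj[iu] = (rng.random(len(iu[0])) < p).astype(np.int8)
    adj += adj.T
    return CoexpressionNetwork(genes, adj)


def gnm_net(n, m, rng, prefix="g"):
    """Uniform random network with exactly n genes and m edges."""
    genes = [f"{prefix}{i}" for i in range(n)]
    iu = np.array(np.triu_indices(n, k=1)).T
    chosen = iu[rng.choice(len(iu), size=m, replace=False)]
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in chosen:
        adj[i, j] = adj[j, i] = 1
    return CoexpressionNetwork(genes, adj)


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        ["gA", "gB", "gC"],
        ["s1", "s2"],
        condition="A",
    )
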